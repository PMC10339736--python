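"""Perturbative ionization/attachment: first order, (D) correction, scaling."""

import numpy as np
import pytest

from dhipea.cisd_ipea import (
    apply_dh_scaling,
    build_V_i_ab,
    build_V_ij_a,
    first_order_states,
    vea_correction,
    vip_correction,
)
from dhipea.config_reference import HARTREE_TO_EV, FunctionalConfig, ReferenceState
from dhipea.fixtures import dense_selfenergy_oracle, make_toy
from dhipea.mp2 import DegenerateReferenceError, prepare_mp2
from conftest import seeded_toys


def _func(c_os, c_ss, ansatz="cisd"):
    return FunctionalConfig(name="test-dh", family="global_DH", alpha_x=1.0,
                            second_order_scales=(c_os, c_ss), ansatz=ansatz,
                            n_empirical_params=0)


class TestFirstOrderStates:
    def test_vip_is_negative_homo_energy(self, toy47):
        [(orb, w1, vec)] = first_order_states(toy47.ref, "ip", 1)
        assert orb == toy47.n_occ - 1
        assert w1 == -toy47.eps_occ[-1]
        assert w1 * HARTREE_TO_EV > 0
        assert vec[orb] == 1.0 and np.sum(vec != 0) == 1

    def test_half_hartree_is_13_6_eV(self):
        ref = ReferenceState(np.eye(2), np.array([-0.5, 0.5]), 0, 1, 1,
                             _func(1, 1))
        [(orb, w1, _)] = first_order_states(ref, "ip", 1)
        assert w1 * HARTREE_TO_EV == pytest.approx(13.6057, abs=1e-4)

    def test_ea_is_lumo_energy(self, toy47):
        [(orb, w1, _)] = first_order_states(toy47.ref, "ea", 1)
        assert orb == 0
        assert w1 == toy47.eps_virt[0]

    def test_degenerate_homo_stable_order(self):
        eps = np.array([-1.0, -0.5, -0.5, 0.4, 0.8])
        ref = ReferenceState(np.eye(5), eps, 0, 3, 2, _func(1, 1))
        states = first_order_states(ref, "ip", 2)
        assert [s[0] for s in states] == [2, 1]
        assert states[0][1] == states[1][1] == 0.5

    def test_too_many_states_rejected(self, toy47):
        with pytest.raises(ValueError, match="active occupied"):
            first_order_states(toy47.ref, "ip", toy47.n_occ + 1)


class TestVIntermediates:
    def test_zero_factors_zero_v(self):
        toy = make_toy(2, 3, 5, seed=0, gap_min=0.8)
        toy.df.j_oo[...] = 0.0
        toy.df.j_ov[...] = 0.0
        v = build_V_ij_a(toy.df, toy.eps_occ, toy.eps_virt, 1)
        assert np.all(v == 0.0)

    def test_v_ij_a_matches_configuration_sum(self, toy47):
        """V[i,j,a] = (ki|aj) / (e_k + e_a - e_i - e_j) against dense ERIs."""
        toy = toy47
        k = toy.n_occ - 1
        eri = np.tensordot(toy.j_full, toy.j_full, axes=([2], [2]))
        eps = toy.ref.orbital_energies
        v = build_V_ij_a(toy.df, toy.eps_occ, toy.eps_virt, k)
        n_o = toy.n_occ
        for i in range(n_o):
            for j in range(n_o):
                for a in range(toy.n_virt):
                    ref = eri[k, i, n_o + a, j] / (
                        eps[k] + eps[n_o + a] - eps[i] - eps[j])
                    assert v[i, j, a] == pytest.approx(ref, abs=1e-12)

    def test_v_i_ab_matches_and_touches_only_target_slice(self, toy47):
        toy = make_toy(3, 4, 10, seed=17, gap_min=0.8)
        c = 1
        eri = np.tensordot(toy.j_full, toy.j_full, axes=([2], [2]))
        eps = toy.ref.orbital_energies
        v = build_V_i_ab(toy.df, toy.eps_occ, toy.eps_virt, c)
        n_o = toy.n_occ
        for i in range(n_o):
            for a in range(toy.n_virt):
                for b in range(toy.n_virt):
                    ref = eri[n_o + c, n_o + a, i, n_o + b] / (
                        eps[n_o + c] + eps[i] - eps[n_o + a] - eps[n_o + b])
                    assert v[i, a, b] == pytest.approx(ref, abs=1e-12)
        assert set(toy.df.vv_slice_log) == {c}

    def test_minimal_toy_hand_value(self, toy_minimal):
        """1x1 case: V = (kk|ak)/(e_a - e_k) by hand algebra."""
        toy = toy_minimal
        eri = np.tensordot(toy.j_full, toy.j_full, axes=([2], [2]))
        eps = toy.ref.orbital_energies
        v = build_V_ij_a(toy.df, toy.eps_occ, toy.eps_virt, 0)
        assert v[0, 0, 0] == pytest.approx(
            eri[0, 0, 1, 0] / (eps[1] - eps[0]), abs=1e-14)

    def test_invalid_targets_rejected(self, toy_small):
        with pytest.raises(IndexError):
            build_V_ij_a(toy_small.df, toy_small.eps_occ, toy_small.eps_virt,
                         toy_small.n_occ)
        with pytest.raises(IndexError):
            build_V_i_ab(toy_small.df, toy_small.eps_occ, toy_small.eps_virt,
                         toy_small.n_virt)


class TestCorrections:
    def test_koopmans_limit_exact(self, toy47):
        mp2ws = prepare_mp2(toy47.df, toy47.eps_occ, toy47.eps_virt)
        for k in range(toy47.n_occ):
            d = vip_correction(toy47.df, mp2ws, k)
            res = apply_dh_scaling(-toy47.eps_occ[k], d, _func(0.0, 0.0),
                                   "ip", k)
            assert res.omega_final == -toy47.eps_occ[k]

    def test_minimal_toy_hand_closed_form(self, toy_minimal):
        """1 occ / 1 virt: the correction reduces to two scalar terms, both
        opposite-spin (a same-spin pair cannot exist in one spatial orbital)."""
        toy = toy_minimal
        eri = np.tensordot(toy.j_full, toy.j_full, axes=([2], [2]))
        e_k, e_a = toy.ref.orbital_energies
        expected = -(eri[0, 0, 1, 0] ** 2 / (e_a - e_k)
                     + eri[0, 1, 0, 1] ** 2 / (2 * (e_k - e_a)))
        mp2ws = prepare_mp2(toy.df, toy.eps_occ, toy.eps_virt)
        d_os, d_ss = vip_correction(toy.df, mp2ws, 0)
        assert d_os == pytest.approx(expected, abs=1e-14)
        assert d_ss == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("channel", ["ip", "ea"])
    def test_matches_selfenergy_oracle_with_spin_split(self, toy47, channel):
        mp2ws = prepare_mp2(toy47.df, toy47.eps_occ, toy47.eps_virt)
        n = toy47.n_occ if channel == "ip" else toy47.n_virt
        for t in range(n):
            oracle = dense_selfenergy_oracle(toy47, t, channel)
            got = (vip_correction(toy47.df, mp2ws, t) if channel == "ip"
                   else vea_correction(toy47.df, mp2ws, t))
            assert got[0] == pytest.approx(oracle.d_os, abs=1e-10)
            assert got[1] == pytest.approx(oracle.d_ss, abs=1e-10)

    def test_size_intensivity_identical_fragments(self):
        mono = make_toy(3, 4, 12, seed=11, gap_min=0.8)
        dim = make_toy(3, 4, 12, seed=11, gap_min=0.8, fragments=2)
        mws = prepare_mp2(mono.df, mono.eps_occ, mono.eps_virt)
        dws = prepare_mp2(dim.df, dim.eps_occ, dim.eps_virt)
        for k in range(mono.n_occ):
            # stable interleave: fragment-A copy of monomer orbital k sits at 2k
            dm, dd = vip_correction(mono.df, mws, k), vip_correction(dim.df, dws, 2 * k)
            assert abs(dm[0] - dd[0]) < 1e-8 and abs(dm[1] - dd[1]) < 1e-8
        for c in range(mono.n_virt):
            dm, dd = vea_correction(mono.df, mws, c), vea_correction(dim.df, dws, 2 * c)
            assert abs(dm[0] - dd[0]) < 1e-8 and abs(dm[1] - dd[1]) < 1e-8

    def test_linearity_in_os_scale(self, toy_small):
        """The scaled correction is linear in c_os at fixed c_ss."""
        mp2ws = prepare_mp2(toy_small.df, toy_small.eps_occ, toy_small.eps_virt)
        d = vea_correction(toy_small.df, mp2ws, 0)
        w1 = toy_small.eps_virt[0]
        finals = [apply_dh_scaling(w1, d, _func(c, 0.5), "ea", 0).omega_final
                  for c in (0.0, 0.6, 1.2)]
        assert finals[2] - finals[1] == pytest.approx(finals[1] - finals[0],
                                                      abs=1e-14)

    def test_degenerate_target_denominator_aborts(self):
        """Force e_k + e_a - e_i - e_j = 0 for the HOMO and expect an abort."""
        from dhipea.mp2 import MP2Workspace

        toy = make_toy(2, 2, 6, seed=4, gap_min=0.8)
        eps_o = np.array([-1.0, -0.6])
        eps_v = np.array([0.2, 2 * eps_o[0] - eps_o[1]])  # resonant level
        ws = MP2Workspace(eps_occ=eps_o, eps_virt=eps_v, e_os=0.0, e_ss=0.0,
                          e_scaled=0.0, scales=(1.0, 1.0))
        with pytest.raises(DegenerateReferenceError):
            vip_correction(toy.df, ws, 1)


class TestApplyDhScaling:
    def test_arithmetic(self):
        res = apply_dh_scaling(0.5, (-0.01, -0.002), _func(1.3, 0.0), "ip", 0)
        assert res.omega_final == pytest.approx(0.5 - 0.013, abs=1e-15)
        assert res.final_eV == pytest.approx(res.omega_final * HARTREE_TO_EV)
        assert res.pole_strength == 1.0
        assert res.iterations == 0

    def test_unit_scales_reproduce_wavefunction_result(self):
        res = apply_dh_scaling(0.5, (-0.01, -0.002), _func(1.0, 1.0), "ip", 0)
        assert res.omega_final == pytest.approx(0.5 - 0.012, abs=1e-15)

    def test_global_single_parameter_scaling(self):
        a_c = 0.36
        res = apply_dh_scaling(0.5, (-0.01, -0.002), _func(a_c, a_c), "ip", 0)
        assert res.omega_final == pytest.approx(0.5 + a_c * -0.012, abs=1e-15)

    def test_hybrid_functional_rejected(self):
        hyb = FunctionalConfig(name="h", family="global_hybrid", alpha_x=0.25,
                               second_order_scales=(0.0, 0.0), ansatz="none",
                               n_empirical_params=1)
        with pytest.raises(ValueError, match="no second-order"):
            apply_dh_scaling(0.5, (-0.01, 0.0), hyb)


def test_os_ss_completeness_across_seeds():
    """OS + SS parts reassemble the unscaled oracle total on several toys."""
    for toy in seeded_toys(4, start_seed=40):
        mp2ws = prepare_mp2(toy.df, toy.eps_occ, toy.eps_virt)
        oracle = dense_selfenergy_oracle(toy, toy.n_occ - 1, "ip")
        d_os, d_ss = vip_correction(toy.df, mp2ws, toy.n_occ - 1)
        assert d_os + d_ss == pytest.approx(oracle.d_os + oracle.d_ss,
                                            abs=1e-10)
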