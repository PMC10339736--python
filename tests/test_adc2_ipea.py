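"""Folded sigma builds, Davidson root following, and pole strengths."""

import numpy as np
import pytest

from dhipea.adc2_ipea import (
    RootLostError,
    pole_strength,
    prepare_sigma_workspace,
    sigma_ea,
    sigma_ip,
    solve_state,
)
from dhipea.cisd_ipea import vip_correction
from dhipea.fixtures import dense_adc2_oracle, make_toy
from dhipea.mp2 import prepare_mp2
from conftest import seeded_toys

SCALES = (1.3, 0.4)


def dense_folded_operator(toy, channel, scales, omega):
    """Oracle route: reconstruct the unfolded spin-orbital matrix from its
    eigendecomposition, fold the doubles block analytically at ``omega``,
    and return the alpha-spin singles block (== the spatial operator)."""
    orc = dense_adc2_oracle(toy, channel, scales)
    H = (orc.vectors * orc.omegas) @ orc.vectors.T
    ns = orc.n_singles
    h_ss = H[:ns, :ns]
    u = H[:ns, ns:]
    cfg_e = np.diag(H[ns:, ns:])
    folded = h_ss + u @ np.diag(1.0 / (omega - cfg_e)) @ u.T
    return folded[0::2, 0::2]


class TestSigmaBuilds:
    def test_zero_scales_first_order_diagonal(self, toy_small):
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, "ip", (0.0, 0.0))
        c = np.array([0.3, -0.5, 0.8])
        np.testing.assert_allclose(sigma_ip(c, 0.7, ws),
                                   -toy_small.eps_occ * c, atol=1e-15)
        ws_ea = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                        toy_small.eps_virt, "ea", (0.0, 0.0))
        c = np.array([0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(sigma_ea(c, 0.2, ws_ea),
                                   toy_small.eps_virt * c, atol=1e-15)

    @pytest.mark.parametrize("channel", ["ip", "ea"])
    def test_matches_dense_folded_matrix_vector(self, toy_small, channel):
        """sigma(c, w) equals the dense unfolded matrix with its doubles
        block folded analytically at the same omega, applied to c."""
        toy = toy_small
        ws = prepare_sigma_workspace(toy.df, toy.eps_occ, toy.eps_virt,
                                     channel, SCALES)
        omega = 0.9 if channel == "ip" else 0.35
        op = dense_folded_operator(toy, channel, SCALES, omega)
        rng = np.random.default_rng(1)
        c = rng.standard_normal(op.shape[0])
        got = (sigma_ip if channel == "ip" else sigma_ea)(c, omega, ws)
        np.testing.assert_allclose(got, op @ c, atol=1e-12)

    def test_linearity_and_additivity(self, toy_small):
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, "ip", SCALES)
        rng = np.random.default_rng(2)
        c1, c2 = rng.standard_normal((2, 3))
        w = 0.8
        np.testing.assert_allclose(sigma_ip(2 * c1, w, ws),
                                   2 * sigma_ip(c1, w, ws), atol=1e-13)
        np.testing.assert_allclose(sigma_ip(c1 + c2, w, ws),
                                   sigma_ip(c1, w, ws) + sigma_ip(c2, w, ws),
                                   atol=1e-13)

    def test_ip_path_requests_no_vv_slices(self, toy_small):
        toy = make_toy(3, 4, 12, seed=31, gap_min=0.8)
        ws = prepare_sigma_workspace(toy.df, toy.eps_occ, toy.eps_virt,
                                     "ip", SCALES)
        for t in range(toy.n_occ):
            solve_state(ws, t)
        assert toy.df.vv_slice_log == []


class TestSolveState:
    def test_koopmans_limit_single_iteration(self, toy47):
        ws = prepare_sigma_workspace(toy47.df, toy47.eps_occ, toy47.eps_virt,
                                     "ip", (0.0, 0.0))
        for t in range(toy47.n_occ):
            st = solve_state(ws, t)
            assert st.converged and st.iterations == 1
            assert st.omega == -toy47.eps_occ[t]
            assert abs(st.vector[t]) == 1.0

    @pytest.mark.parametrize("channel", ["ip", "ea"])
    def test_matches_dense_oracle_all_targets(self, toy47, channel):
        orc = dense_adc2_oracle(toy47, channel, SCALES)
        ws = prepare_sigma_workspace(toy47.df, toy47.eps_occ, toy47.eps_virt,
                                     channel, SCALES)
        n = toy47.n_occ if channel == "ip" else toy47.n_virt
        for t in range(n):
            st = solve_state(ws, t)
            w_ref, _, _ = orc.root_for(t)
            assert st.converged
            assert st.omega == pytest.approx(w_ref, abs=1e-6)
            assert np.linalg.norm(st.vector) == pytest.approx(1.0, abs=1e-12)

    def test_root_following_returns_non_lowest_root(self, toy47):
        """A deep target is not the lowest root; the solver must track it."""
        t = toy47.n_occ - 3
        orc = dense_adc2_oracle(toy47, "ip", SCALES)
        w_ref, _, rank = orc.root_for(t)
        assert rank > 0  # genuinely not the lowest eigenvalue
        ws = prepare_sigma_workspace(toy47.df, toy47.eps_occ, toy47.eps_virt,
                                     "ip", SCALES)
        st = solve_state(ws, t)
        assert st.omega == pytest.approx(w_ref, abs=1e-6)

    def test_precompute_happens_once_for_many_states(self, toy_small):
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, "ip", SCALES)
        for t in range(3):
            solve_state(ws, t)
        assert ws.precompute_count == 1

    def test_continuity_with_perturbative_ansatz(self, toy47):
        """As the second-order block is scaled down, iterative and
        perturbative results agree to first order (Richardson check)."""
        k = toy47.n_occ - 1
        mp2ws = prepare_mp2(toy47.df, toy47.eps_occ, toy47.eps_virt)
        d_os, d_ss = vip_correction(toy47.df, mp2ws, k)

        def gap(t):
            ws = prepare_sigma_workspace(toy47.df, toy47.eps_occ,
                                         toy47.eps_virt, "ip", (t, t))
            st = solve_state(ws, k, conv_energy=1e-12, resid_tol=1e-11)
            cisd = -toy47.eps_occ[k] + t * (d_os + d_ss)
            return st.omega - cisd

        d1, d2 = gap(0.1), gap(0.05)
        assert d1 / d2 == pytest.approx(4.0, rel=0.15)


class TestPoleStrength:
    def test_unity_without_second_order(self, toy_small):
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, "ea", (0.0, 0.0))
        st = solve_state(ws, 0)
        assert pole_strength(st, ws) == 1.0

    @pytest.mark.parametrize("channel", ["ip", "ea"])
    def test_matches_oracle_singles_norm(self, toy_small, channel):
        orc = dense_adc2_oracle(toy_small, channel, SCALES)
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, channel, SCALES)
        n = toy_small.n_occ if channel == "ip" else toy_small.n_virt
        for t in range(n):
            st = solve_state(ws, t, conv_energy=1e-11, resid_tol=1e-10)
            _, p_ref, _ = orc.root_for(t)
            assert pole_strength(st, ws) == pytest.approx(p_ref, abs=1e-8)

    def test_monotone_decrease_with_growing_os_scale(self, toy_small):
        vals = []
        for c_os in (0.5, 1.0, 1.5):
            ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                         toy_small.eps_virt, "ip", (c_os, 0.0))
            st = solve_state(ws, toy_small.n_occ - 1,
                             conv_energy=1e-11, resid_tol=1e-10)
            orc = dense_adc2_oracle(toy_small, "ip", (c_os, 0.0))
            _, p_ref, _ = orc.root_for(toy_small.n_occ - 1)
            p = pole_strength(st, ws)
            assert p == pytest.approx(p_ref, abs=1e-8)
            vals.append(p)
        assert vals[0] > vals[1] > vals[2]

    def test_unconverged_state_rejected(self, toy_small):
        ws = prepare_sigma_workspace(toy_small.df, toy_small.eps_occ,
                                     toy_small.eps_virt, "ip", SCALES)
        st = solve_state(ws, 0, max_iter=0)
        assert not st.converged
        with pytest.raises(ValueError, match="unconverged"):
            pole_strength(st, ws)


def test_iterative_oracle_agreement_across_seeds():
    """Folded-solver vs dense-oracle agreement on a sweep of seeded toys."""
    for toy in seeded_toys(3, start_seed=60,
                           sizes=((3, 4, 10), (2, 5, 12), (4, 4, 14))):
        for channel in ("ip", "ea"):
            orc = dense_adc2_oracle(toy, channel, SCALES)
            ws = prepare_sigma_workspace(toy.df, toy.eps_occ, toy.eps_virt,
                                         channel, SCALES)
            n = toy.n_occ if channel == "ip" else toy.n_virt
            for t in range(n):
                st = solve_state(ws, t)
                w_ref, _, _ = orc.root_for(t)
                assert abs(st.omega - w_ref) < 1e-6
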