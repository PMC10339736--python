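"""Synthetic reference states and dense brute-force oracles.

Every numerical claim in this package is anchored to the objects built here:

* :func:`make_toy_reference` draws a seeded, gapped synthetic closed-shell
  reference (orbital energies in narrow bands around a guaranteed HOMO-LUMO
  gap, random low-rank three-center factors of magnitude ``sigma``) with an
  optional block-diagonal multi-fragment layout whose cross-fragment
  integrals are exactly zero.
* :func:`dense_selfenergy_oracle` evaluates the diagonal, frequency-
  independent second-order self-energy of a target orbital by an explicit
  spin-orbital sum over all 2h1p and 2p1h configurations.
* :func:`dense_adc2_oracle` assembles the full spin-orbital singles(+)doubles
  secular matrix (static second-order singles block, first-order couplings
  scaled per spin class, bare doubles diagonal) and diagonalizes it densely.

The oracles share no contraction kernels with the production modules: they
work from antisymmetrized spin-orbital integrals reconstructed directly from
the toy's raw factors with plain ``numpy`` operations.  The pseudo-random
stream is ``numpy.random.default_rng`` (PCG64), fixed here by name so the
fixtures are stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config_reference import (
    AOIntegralHandles,
    FunctionalConfig,
    MoleculeSpec,
    ReferenceState,
)
from .df_integrals import DFTensor

__all__ = [
    "ToyReference",
    "make_toy",
    "make_toy_reference",
    "ToyScfBackend",
    "OracleCorrection",
    "dense_selfenergy_oracle",
    "AdcDenseOracle",
    "dense_adc2_oracle",
]

# Energy bands of the synthetic spectrum (hartree).  Occupied energies are
# drawn in [-1.0, -0.7] and virtuals in a 0.3-wide band starting gap_min
# above the HOMO, so every 1h (1p) level stays well separated from the
# 2h1p (2p1h) quasi-continuum once the gap is a few tenths of a hartree --
# the single-root-dominant regime these methods target.
_OCC_BAND = (-1.0, -0.7)
_VIRT_SPREAD = 0.3

_TOY_FUNCTIONAL = FunctionalConfig(
    name="toy-reference",
    family="global_DH",
    alpha_x=1.0,
    second_order_scales=(1.0, 1.0),
    ansatz="adc2",
    n_empirical_params=0,
    citation="synthetic fixture; not a published functional",
)


@dataclass
class ToyReference:
    """A synthetic reference plus the raw data the dense oracles need."""

    ref: ReferenceState
    df: DFTensor
    j_full: np.ndarray  # (n_mo, n_mo, n_aux), symmetric in the MO pair
    n_occ: int
    n_virt: int
    n_aux: int
    seed: int
    gap_min: float
    sigma: float
    fragments: int

    @property
    def eps_occ(self) -> np.ndarray:
        return self.ref.eps_occ

    @property
    def eps_virt(self) -> np.ndarray:
        return self.ref.eps_virt


def _fragment_spectrum(rng: np.random.Generator, n_occ: int, n_virt: int,
                       gap_min: float) -> tuple[np.ndarray, np.ndarray]:
    eps_o = np.sort(rng.uniform(*_OCC_BAND, size=n_occ))
    lo = eps_o.max() + gap_min
    eps_v = np.sort(rng.uniform(lo, lo + _VIRT_SPREAD, size=n_virt))
    return eps_o, eps_v


def make_toy(
    n_occ: int,
    n_virt: int,
    n_aux: int,
    seed: int,
    gap_min: float = 0.2,
    sigma: float = 0.05,
    fragments: int = 1,
) -> ToyReference:
    """Build a deterministic synthetic reference with the stated structure.

    With ``fragments > 1`` the toy is a block-diagonal replica of one
    fragment of the given sizes: identical per-fragment spectra and factors,
    exactly zero cross-fragment entries (orbital order is re-sorted by energy
    with a stable permutation so the reference invariants hold).
    """
    if min(n_occ, n_virt, n_aux) < 1 or fragments < 1:
        raise ValueError("all sizes must be >= 1")
    if gap_min <= 0:
        raise ValueError(f"gap construction infeasible: gap_min={gap_min}")
    rng = np.random.default_rng(seed)
    eps_o_f, eps_v_f = _fragment_spectrum(rng, n_occ, n_virt, gap_min)
    raw = rng.normal(0.0, sigma, size=(n_occ + n_virt, n_occ + n_virt, n_aux))
    j_f = 0.5 * (raw + raw.transpose(1, 0, 2))

    k = fragments
    n_mo_f = n_occ + n_virt
    n_mo = k * n_mo_f
    n_aux_tot = k * n_aux
    # fragment-by-fragment layout: occupieds of all fragments first
    eps = np.empty(n_mo)
    j_full = np.zeros((n_mo, n_mo, n_aux_tot))
    occ_idx, virt_idx = [], []
    for f in range(k):
        o0, v0 = f * n_occ, k * n_occ + f * n_virt
        occ_idx.extend(range(o0, o0 + n_occ))
        virt_idx.extend(range(v0, v0 + n_virt))
        eps[o0:o0 + n_occ] = eps_o_f
        eps[v0:v0 + n_virt] = eps_v_f
        rows = list(range(o0, o0 + n_occ)) + list(range(v0, v0 + n_virt))
        q0 = f * n_aux
        j_full[np.ix_(rows, rows, range(q0, q0 + n_aux))] = j_f
    # stable energy sort within each block (interleaves identical fragments)
    occ_perm = [occ_idx[t] for t in np.argsort(eps[occ_idx], kind="stable")]
    virt_perm = [virt_idx[t] for t in np.argsort(eps[virt_idx], kind="stable")]
    perm = np.array(occ_perm + virt_perm)
    eps = eps[perm]
    j_full = j_full[np.ix_(perm, perm)]

    n_occ_tot, n_virt_tot = k * n_occ, k * n_virt
    ref = ReferenceState(
        mo_coefficients=np.eye(n_mo),
        orbital_energies=eps,
        n_frozen_core=0,
        n_occupied_active=n_occ_tot,
        n_virtual=n_virt_tot,
        produced_by=_TOY_FUNCTIONAL,
    )
    occ = slice(0, n_occ_tot)
    virt = slice(n_occ_tot, n_mo)
    j_vv = j_full[virt, virt]

    df = DFTensor(
        j_oo=j_full[occ, occ].copy(),
        j_ov=j_full[occ, virt].copy(),
        n_aux_effective=n_aux_tot,
        _vv_provider=lambda b: j_vv[:, b, :],
    )
    return ToyReference(ref=ref, df=df, j_full=j_full, n_occ=n_occ_tot,
                        n_virt=n_virt_tot, n_aux=n_aux_tot, seed=seed,
                        gap_min=gap_min, sigma=sigma, fragments=k)


def make_toy_reference(
    n_occ: int,
    n_virt: int,
    n_aux: int,
    seed: int,
    gap_min: float = 0.2,
    sigma: float = 0.05,
    fragments: int = 1,
) -> tuple[ReferenceState, DFTensor]:
    """Deterministic (ReferenceState, DFTensor) pair; see :func:`make_toy`."""
    toy = make_toy(n_occ, n_virt, n_aux, seed, gap_min, sigma, fragments)
    return toy.ref, toy.df


class ToyScfBackend:
    """SCF-backend adapter over synthetic AO data (no real SCF is run).

    Generates a gapped spectrum and random AO three-center factors that are
    consistent with a random orthogonal MO coefficient matrix and a random
    SPD auxiliary metric, so the full production pipeline (metric
    conditioning, AO->MO transformation) is exercised end to end.
    """

    def __init__(self, n_occ: int, n_virt: int, n_aux: int, seed: int,
                 gap_min: float = 0.8, sigma: float = 0.05):
        self.n_occ, self.n_virt, self.n_aux = n_occ, n_virt, n_aux
        self.seed, self.gap_min, self.sigma = seed, gap_min, sigma

    def converge(self, mol: Optional[MoleculeSpec], func: FunctionalConfig):
        rng = np.random.default_rng(self.seed)
        n_mo = self.n_occ + self.n_virt
        eps_o, eps_v = _fragment_spectrum(rng, self.n_occ, self.n_virt,
                                          self.gap_min)
        mo_energy = np.concatenate([eps_o, eps_v])
        raw = rng.normal(0.0, self.sigma, size=(n_mo, n_mo, self.n_aux))
        j_mo = 0.5 * (raw + raw.transpose(1, 0, 2))
        C, _ = np.linalg.qr(rng.standard_normal((n_mo, n_mo)))
        # AO factors consistent with C (orthogonal) and an SPD metric W:
        # I_ao = C j_mo C^T W^(1/2)  so that  I_ao W^(-1/2) transforms back.
        a = rng.standard_normal((self.n_aux, self.n_aux))
        W = a @ a.T + self.n_aux * np.eye(self.n_aux)
        w, U = np.linalg.eigh(W)
        W_half = (U * np.sqrt(w)) @ U.T
        i_ao = np.einsum("mp,pqP,nq,PQ->mnQ", C, j_mo, C, W_half)
        handles = AOIntegralHandles(three_center=i_ao, two_center=W)
        return C, mo_energy, self.n_occ, handles


class HandBuiltBackend:
    """Identity adapter: returns exactly the arrays it was constructed with."""

    def __init__(self, mo_coeff, mo_energy, n_occ, handles: AOIntegralHandles):
        self._data = (np.asarray(mo_coeff, dtype=float),
                      np.asarray(mo_energy, dtype=float), int(n_occ), handles)

    def converge(self, mol, func):
        return self._data


# ----------------------------------------------------------------------------
# dense spin-orbital machinery (oracle-only code path)
# ----------------------------------------------------------------------------

def _eri_spatial(toy: ToyReference) -> np.ndarray:
    """(pq|rs) in the spatial MO basis, reconstructed from the raw factors."""
    return np.tensordot(toy.j_full, toy.j_full, axes=([2], [2]))


def _antisym_so(toy: ToyReference) -> tuple[np.ndarray, np.ndarray]:
    """Antisymmetrized <pq||rs> over spin orbitals (index 2p+spin) + energies."""
    eri = _eri_spatial(toy)
    n = eri.shape[0]
    phys = eri.transpose(0, 2, 1, 3)  # <pq|rs> = (pr|qs)
    so = np.zeros((2 * n,) * 4)
    for s1 in (0, 1):
        for s2 in (0, 1):
            so[s1::2, s2::2, s1::2, s2::2] = phys
    anti = so - so.transpose(0, 1, 3, 2)
    eps_so = np.repeat(toy.ref.orbital_energies, 2)
    return anti, eps_so


@dataclass
class OracleCorrection:
    """OS/SS-resolved second-order correction from the dense oracle."""

    d_os: float  # hartree, enters as omega_first + c_os*d_os + c_ss*d_ss
    d_ss: float
    scaled: float


def dense_selfenergy_oracle(
    toy: ToyReference,
    orbital: int,
    channel: str,
    scales: tuple[float, float] = (1.0, 1.0),
) -> OracleCorrection:
    """Diagonal frequency-independent second-order self-energy, brute force.

    Explicit spin-orbital sums over all 2h1p and 2p1h configurations at
    omega fixed to the target orbital energy; a configuration is same-spin
    when every summed spin matches the target's, opposite-spin otherwise.
    """
    if toy.n_occ > 6 or toy.n_virt > 8:
        raise ValueError("oracle size guard: occ <= 6 and virt <= 8 required")
    anti, eps = _antisym_so(toy)
    n_occ_so = 2 * toy.n_occ
    n_so = 2 * (toy.n_occ + toy.n_virt)
    occ = range(n_occ_so)
    virt = range(n_occ_so, n_so)
    if channel == "ip":
        t = 2 * orbital  # alpha spin orbital of the target occupied orbital
    elif channel == "ea":
        t = n_occ_so + 2 * orbital
    else:
        raise ValueError(f"unknown channel {channel!r}")
    ts = t % 2
    s_os = s_ss = 0.0
    for i in occ:
        for j in occ:
            for a in virt:
                u = anti[t, a, i, j]  # <t a || i j>
                if u == 0.0:
                    continue
                den = eps[t] + eps[a] - eps[i] - eps[j]
                if den == 0.0:
                    raise ZeroDivisionError("vanishing 2h1p denominator")
                val = 0.5 * u * u / den
                if i % 2 == j % 2 == a % 2 == ts:
                    s_ss += val
                else:
                    s_os += val
    for i in occ:
        for a in virt:
            for b in virt:
                u = anti[t, i, a, b]  # <t i || a b>
                if u == 0.0:
                    continue
                den = eps[t] + eps[i] - eps[a] - eps[b]
                if den == 0.0:
                    raise ZeroDivisionError("vanishing 2p1h denominator")
                val = 0.5 * u * u / den
                if i % 2 == a % 2 == b % 2 == ts:
                    s_ss += val
                else:
                    s_os += val
    sign = -1.0 if channel == "ip" else 1.0
    d_os, d_ss = sign * s_os, sign * s_ss
    c_os, c_ss = scales
    return OracleCorrection(d_os=d_os, d_ss=d_ss,
                            scaled=c_os * d_os + c_ss * d_ss)


@dataclass
class AdcDenseOracle:
    """Dense diagonalization of the unfolded singles(+)doubles matrix.

    ``omegas``/``vectors`` hold the full eigenspectrum (ascending);
    ``n_singles`` spin-orbital singles components lead each eigenvector.
    """

    channel: str
    omegas: np.ndarray
    vectors: np.ndarray  # columns
    n_singles: int
    n_spatial_singles: int

    def singles_weight(self, root: int) -> float:
        v = self.vectors[:, root]
        return float(np.sum(v[: self.n_singles] ** 2))

    def root_for(self, orbital: int) -> tuple[float, float, int]:
        """(omega, pole strength, rank) of the root dominated by ``orbital``.

        ``rank`` is the position of the root among all eigenvalues in
        ascending order (0-based); weight is summed over both spin copies of
        the target spatial orbital.
        """
        w = (self.vectors[2 * orbital, :] ** 2
             + self.vectors[2 * orbital + 1, :] ** 2)
        root = int(np.argmax(w))
        return float(self.omegas[root]), self.singles_weight(root), root


def dense_adc2_oracle(
    toy: ToyReference,
    channel: str,
    scales: tuple[float, float] = (1.0, 1.0),
) -> AdcDenseOracle:
    """Build and diagonalize the explicit spin-orbital secular matrix.

    Singles block: first-order diagonal plus the static second-order
    self-energy (each spin class weighted by its scale).  Doubles: all
    2h1p (ionization) or 2p1h (attachment) spin-orbital configurations with
    bare diagonal energies, coupled in first order with each coupling scaled
    by the square root of its spin-class weight -- so that folding the
    doubles out reproduces the scaled effective Jacobian exactly.
    """
    if toy.n_occ > 6 or toy.n_virt > 8:
        raise ValueError("oracle size guard: occ <= 6 and virt <= 8 required")
    anti, eps = _antisym_so(toy)
    c_os, c_ss = scales
    n_occ_so = 2 * toy.n_occ
    n_so = 2 * (toy.n_occ + toy.n_virt)
    occ = list(range(n_occ_so))
    virt = list(range(n_occ_so, n_so))

    if channel == "ip":
        singles = occ
        sign = -1.0
        # 2h1p configurations (i<j, a)
        configs = [(i, j, a) for i in occ for j in occ if j > i for a in virt]
        cfg_energy = np.array([-eps[i] - eps[j] + eps[a] for i, j, a in configs])
        same_spin = np.array([i % 2 == j % 2 == a % 2 for i, j, a in configs])
        u = np.zeros((len(singles), len(configs)))
        for col, (i, j, a) in enumerate(configs):
            for row, q in enumerate(singles):
                u[row, col] = anti[i, j, q, a]
        # static block: 2p1h fold at the reference orbital energies
        comp = [(k, a, b) for k in occ for a in virt for b in virt]
        comp_ss = np.array([k % 2 == a % 2 == b % 2 for k, a, b in comp])
        g = np.array([[anti[q, k, a, b] for k, a, b in comp] for q in singles])
        dmat = np.array([[eps[q] + eps[k] - eps[a] - eps[b] for k, a, b in comp]
                         for q in singles])
        static_sign = -0.25
    else:
        singles = virt
        sign = +1.0
        configs = [(a, b, i) for a in virt for b in virt if b > a for i in occ]
        cfg_energy = np.array([eps[a] + eps[b] - eps[i] for a, b, i in configs])
        same_spin = np.array([a % 2 == b % 2 == i % 2 for a, b, i in configs])
        u = np.zeros((len(singles), len(configs)))
        for col, (a, b, i) in enumerate(configs):
            for row, q in enumerate(singles):
                u[row, col] = anti[q, i, a, b]
        comp = [(a, i, j) for a in virt for i in occ for j in occ]
        comp_ss = np.array([a % 2 == i % 2 == j % 2 for a, i, j in comp])
        g = np.array([[anti[q, a, i, j] for a, i, j in comp] for q in singles])
        dmat = np.array([[eps[q] + eps[a] - eps[i] - eps[j] for a, i, j in comp]
                         for q in singles])
        static_sign = +0.25

    cls = np.where(same_spin, c_ss, c_os)
    u_scaled = u * np.sqrt(cls)[None, :]

    comp_cls = np.where(comp_ss, c_ss, c_os)
    n_sing = len(singles)
    static = np.zeros((n_sing, n_sing))
    for p in range(n_sing):
        for q in range(p, n_sing):
            val = np.sum(comp_cls * g[p] * g[q] * (1.0 / dmat[p] + 1.0 / dmat[q]))
            static[p, q] = static[q, p] = static_sign * val

    dim = n_sing + len(configs)
    h = np.zeros((dim, dim))
    h[:n_sing, :n_sing] = np.diag(sign * eps[singles]) + static
    h[:n_sing, n_sing:] = u_scaled
    h[n_sing:, :n_sing] = u_scaled.T
    h[n_sing:, n_sing:] = np.diag(cfg_energy)
    omegas, vectors = np.linalg.eigh(h)
    return AdcDenseOracle(channel=channel, omegas=omegas, vectors=vectors,
                          n_singles=n_sing, n_spatial_singles=n_sing // 2)
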