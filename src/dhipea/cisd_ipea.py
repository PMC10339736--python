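"""Perturbative (CIS(D)-based) vertical ionization and attachment energies.

At first order the ionized/attached states of a closed-shell reference are
single Koopmans configurations: the VIP of occupied orbital k is -e_k and the
attachment energy of virtual orbital c is +e_c, with Cartesian unit vectors
as eigenvectors.  The second-order (D) correction evaluated at the target
orbital energy coincides with the diagonal, frequency-independent
second-order self-energy of that orbital; in closed-shell spatial orbitals,
for an occupied target k,

    S_2p1h(k) = sum_iab (ka|ib) [2 (ka|ib) - (kb|ia)] / (e_k + e_i - e_a - e_b)
    S_2h1p(k) = sum_ija (ki|aj) [2 (ki|aj) - (kj|ai)] / (e_k + e_a - e_i - e_j)

and the scaled VIP is  -e_k - [c_os S_os + c_ss S_ss]  with the OS part
collecting the squared direct integrals and the SS part the direct-minus-
exchange products.  The attachment channel mirrors this with an overall +
sign on the self-energy.  The disconnected contributions cancel against the
ground-state MP2 energy and never appear explicitly.

Cost note: with the occupied index fixed at the target, every contraction
here is bounded by N_occ^2 N_virt N_aux (ionization) or N_occ N_virt^2 N_aux
(attachment) -- comparable to one ground-state Fock build -- and the
ionization path touches no virtual-virtual integrals at all.  Attachment
needs the virtual-virtual block only through slices with one index fixed at
the target orbital.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config_reference import HARTREE_TO_EV, FunctionalConfig, ReferenceState
from .df_integrals import DFTensor, contract
from .mp2 import DEGENERACY_TOL, DegenerateReferenceError, MP2Workspace

__all__ = [
    "StateResult",
    "CorrectionWorkspace",
    "first_order_states",
    "build_V_ij_a",
    "build_V_i_ab",
    "vip_correction",
    "vea_correction",
    "apply_dh_scaling",
    "perturbative_states",
]


@dataclass
class StateResult:
    """One ionized or attached state, first order through final scaled value."""

    channel: str  # "ip" | "ea"
    target_orbital: int  # index within the active occupied (IP) / virtual (EA) space
    omega_first: float  # hartree
    omega_D_os: float  # hartree, unscaled opposite-spin (D) part
    omega_D_ss: float  # hartree, unscaled same-spin (D) part
    omega_final: float  # hartree
    final_eV: float
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True
    pole_strength: Optional[float] = None


@dataclass
class CorrectionWorkspace:
    """Intermediates for the (D) correction of a single target state.

    ``v`` holds the first-order doubles coefficients: the 2h1p block
    V_ij^a = (ki|aj)/(e_k + e_a - e_i - e_j) for ionization, or the 2p1h
    block V_i^ab = (ca|ib)/(e_c + e_i - e_a - e_b) for attachment.  The
    X accumulators carry the complementary (Y-type) contribution.
    """

    channel: str
    target_orbital: int
    v: np.ndarray
    v_os: float
    v_ss: float
    x_os: float
    x_ss: float


def first_order_states(
    ref: ReferenceState, channel: str, n_states: int
) -> list[tuple[int, float, np.ndarray]]:
    """Koopmans states: ``[(orbital, omega_first, unit vector), ...]``.

    Ionization returns the ``n_states`` highest active occupied orbitals
    (VIP ascending, i.e. HOMO first); attachment the lowest virtuals.
    Degenerate orbitals keep stable index order.
    """
    if channel == "ip":
        eps = ref.eps_occ
        if n_states > eps.size:
            raise ValueError(
                f"{n_states} ionized states requested but only {eps.size} "
                "active occupied orbitals"
            )
        orbitals = range(eps.size - 1, eps.size - 1 - n_states, -1)
        sign = -1.0
    elif channel == "ea":
        eps = ref.eps_virt
        if n_states > eps.size:
            raise ValueError(
                f"{n_states} attached states requested but only {eps.size} "
                "virtual orbitals"
            )
        orbitals = range(n_states)
        sign = +1.0
    else:
        raise ValueError(f"unknown channel {channel!r} (expected 'ip' or 'ea')")
    out = []
    for orb in orbitals:
        vec = np.zeros(eps.size)
        vec[orb] = 1.0
        out.append((orb, sign * float(eps[orb]), vec))
    return out


def _check_denominator(den: np.ndarray, what: str, tol: float) -> None:
    if np.abs(den).min() < tol:
        raise DegenerateReferenceError(f"vanishing {what} denominator (< {tol:g} E_h)")


def build_V_ij_a(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    k: int,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> np.ndarray:
    """First-order 2h1p coefficients V[i,j,a] for ionization out of orbital k."""
    if not (0 <= k < df.n_occ):
        raise IndexError(f"target orbital {k} is not an active occupied orbital")
    x = contract("iQ,jaQ->ija", df.j_oo[k], df.j_ov)  # (ki|aj)
    den = (eps_occ[k] + eps_virt[None, None, :]
           - eps_occ[:, None, None] - eps_occ[None, :, None])
    _check_denominator(den, "2h1p", degeneracy_tol)
    return x / den


def build_V_i_ab(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    c: int,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> np.ndarray:
    """First-order 2p1h coefficients V[i,a,b] for attachment into orbital c.

    Virtual-virtual integrals enter only through the single slice with one
    index fixed at c.
    """
    if not (0 <= c < df.n_virt):
        raise IndexError(f"target orbital {c} is not a virtual orbital")
    s_c = df.j_vv_slice(c)  # (n_virt, Q) = (ca|Q)
    x = contract("aQ,ibQ->iab", s_c, df.j_ov)  # (ca|ib)
    den = (eps_virt[c] + eps_occ[:, None, None]
           - eps_virt[None, :, None] - eps_virt[None, None, :])
    _check_denominator(den, "2p1h", degeneracy_tol)
    return x / den


def vip_correction(
    df: DFTensor,
    mp2ws: MP2Workspace,
    k: int,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> tuple[float, float]:
    """Unscaled (opposite-spin, same-spin) (D) correction to the VIP of orbital k.

    The returned pair enters the final value as
    ``VIP = -e_k + c_os * d_os + c_ss * d_ss``.
    """
    eps_o, eps_v = mp2ws.eps_occ, mp2ws.eps_virt
    # 2h1p block: holes relax among the occupied space
    x = contract("iQ,jaQ->ija", df.j_oo[k], df.j_ov)  # (ki|aj)
    den = (eps_o[k] + eps_v[None, None, :]
           - eps_o[:, None, None] - eps_o[None, :, None])
    _check_denominator(den, "2h1p", degeneracy_tol)
    t = x / den
    s2h1p_os = float(np.sum(x * t))
    s2h1p_ss = float(np.sum((x - np.swapaxes(x, 0, 1)) * t))
    # 2p1h block: target-orbital row of the ground-state amplitudes (Y-type)
    s2p1h_os = 0.0
    s2p1h_ss = 0.0
    for i in range(df.n_occ):
        g = contract("aQ,bQ->ab", df.j_ov[k], df.j_ov[i])  # (ka|ib)
        d = (eps_o[k] + eps_o[i]) - eps_v[:, None] - eps_v[None, :]
        _check_denominator(d, "2p1h", degeneracy_tol)
        u = g / d
        s2p1h_os += float(np.sum(g * u))
        s2p1h_ss += float(np.sum((g - g.T) * u))
    return -(s2h1p_os + s2p1h_os), -(s2h1p_ss + s2p1h_ss)


def vea_correction(
    df: DFTensor,
    mp2ws: MP2Workspace,
    c: int,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> tuple[float, float]:
    """Unscaled (opposite-spin, same-spin) (D) correction to the attachment
    energy of virtual orbital c: ``EA_attach = e_c + c_os*d_os + c_ss*d_ss``."""
    eps_o, eps_v = mp2ws.eps_occ, mp2ws.eps_virt
    # 2h1p block: (ci|aj) from occupied-virtual factors only
    x = contract("iQ,jaQ->ija", df.j_ov[:, c, :], df.j_ov)  # (ci|aj)
    den = (eps_v[c] + eps_v[None, None, :]
           - eps_o[:, None, None] - eps_o[None, :, None])
    _check_denominator(den, "2h1p", degeneracy_tol)
    t = x / den
    s2h1p_os = float(np.sum(x * t))
    s2h1p_ss = float(np.sum((x - np.swapaxes(x, 0, 1)) * t))
    # 2p1h block: virtual-virtual integrals through the target slice only
    s_c = df.j_vv_slice(c)
    x2 = contract("dQ,ieQ->ide", s_c, df.j_ov)  # (cd|ie)
    den2 = (eps_v[c] + eps_o[:, None, None]
            - eps_v[None, :, None] - eps_v[None, None, :])
    _check_denominator(den2, "2p1h", degeneracy_tol)
    u = x2 / den2
    s2p1h_os = float(np.sum(x2 * u))
    s2p1h_ss = float(np.sum((x2 - np.swapaxes(x2, 1, 2)) * u))
    return (s2h1p_os + s2p1h_os), (s2h1p_ss + s2p1h_ss)


def apply_dh_scaling(
    omega_first: float,
    correction: tuple[float, float],
    func: FunctionalConfig,
    channel: str = "ip",
    target_orbital: int = 0,
) -> StateResult:
    """Assemble the final scaled state from the first-order value and the
    unscaled OS/SS correction parts."""
    if func.is_hybrid:
        raise ValueError(
            f"{func.name}: hybrid functional defines no second-order correction"
        )
    if func.ansatz not in ("cisd", "adc2"):
        raise ValueError(f"{func.name}: unsupported ansatz {func.ansatz!r}")
    c_os, c_ss = func.second_order_scales
    d_os, d_ss = correction
    omega_final = omega_first + c_os * d_os + c_ss * d_ss
    return StateResult(
        channel=channel,
        target_orbital=target_orbital,
        omega_first=omega_first,
        omega_D_os=d_os,
        omega_D_ss=d_ss,
        omega_final=omega_final,
        final_eV=omega_final * HARTREE_TO_EV,
        pole_strength=1.0,  # perturbative ansatz: no doubles admixture
    )


def perturbative_states(
    ref: ReferenceState,
    df: DFTensor,
    mp2ws: MP2Workspace,
    func: FunctionalConfig,
    channel: str,
    n_states: int,
) -> list[StateResult]:
    """All requested states of one channel at the CIS(D)-based level."""
    out = []
    for orb, omega1, _vec in first_order_states(ref, channel, n_states):
        if channel == "ip":
            corr = vip_correction(df, mp2ws, orb)
        else:
            corr = vea_correction(df, mp2ws, orb)
        out.append(apply_dh_scaling(omega1, corr, func, channel, orb))
    return out
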