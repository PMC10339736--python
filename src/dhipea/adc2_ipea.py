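"""Iterative non-Dyson ADC(2)-based ionization and attachment states.

The ionized (attached) states are solved in the 1h (1p) singles space with
the doubles space folded in analytically: the action of the effective,
frequency-dependent Jacobian on a singles vector c is

    sigma(c, w)_i = -e_i c_i + sum_j [ S_ij + F_ij(w) ] c_j        (ionization)
    sigma(c, w)_a = +e_a c_a + sum_b [ S_ab + F_ab(w) ] c_b        (attachment)

where S is the static second-order singles block (the frequency-independent
fold of the complementary particle-hole sector, evaluated at the reference
orbital energies) and F(w) the explicit fold of the 2h1p (2p1h) doubles
space.  Both second-order pieces carry the double-hybrid opposite-/same-spin
scales, so with scales (0, 0) the operator is exactly the first-order
diagonal and the roots are the bare orbital energies.

The N^5 precompute (the static block, an unrestricted-index Y-type build)
happens once per (reference, channel) workspace regardless of how many
states are requested; each solver iteration costs N^4 and the ionization
path touches no virtual-virtual integrals.

The nonlinear problem sigma(c, w) = w c is solved by macro-iterations that
freeze w, run a Davidson eigensolver with maximum-overlap root following,
then update w from the selected Ritz value, until |dw| <= conv_energy
(default 1e-6 hartree) and the residual is below resid_tol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .df_integrals import DFTensor, contract
from .mp2 import DEGENERACY_TOL, DegenerateReferenceError

__all__ = [
    "SigmaWorkspace",
    "IterativeState",
    "RootLostError",
    "prepare_sigma_workspace",
    "sigma_ip",
    "sigma_ea",
    "solve_state",
    "pole_strength",
]

#: paper-level convergence threshold on the state energy (hartree)
CONV_ENERGY = 1e-6
#: residual tolerance on ||sigma(c) - w c||, chosen to under-resolve the
#: energy threshold
RESID_TOL = 1e-5
#: minimum admissible overlap between the followed Ritz vector and its anchor
OVERLAP_FLOOR = 0.3
MAX_SUBSPACE = 20
COLLAPSE_TO = 2


class RootLostError(RuntimeError):
    """Root following failed: no Ritz vector overlaps the anchor sufficiently."""


@dataclass
class SigmaWorkspace:
    """Once-per-job intermediates for one channel of one reference."""

    channel: str  # "ip" | "ea"
    df: DFTensor
    eps_occ: np.ndarray
    eps_virt: np.ndarray
    scales: tuple[float, float]
    static_os: np.ndarray  # unscaled opposite-spin static block
    static_ss: np.ndarray  # unscaled same-spin static block
    degeneracy_tol: float = DEGENERACY_TOL
    precompute_count: int = 1

    @property
    def n_singles(self) -> int:
        return self.eps_occ.size if self.channel == "ip" else self.eps_virt.size

    @property
    def static(self) -> np.ndarray:
        c_os, c_ss = self.scales
        return c_os * self.static_os + c_ss * self.static_ss

    @property
    def diag_first_order(self) -> np.ndarray:
        return -self.eps_occ if self.channel == "ip" else self.eps_virt


@dataclass
class IterativeState:
    """A converged (or flagged) root of the folded nonlinear eigenproblem."""

    channel: str
    target_orbital: int
    omega: float  # hartree
    vector: np.ndarray  # unit-norm singles vector
    residual: float
    iterations: int  # macro-iterations
    converged: bool
    pole_strength: Optional[float] = None


# ----------------------------------------------------------------------------
# workspace preparation (the once-per-job N^5 step)
# ----------------------------------------------------------------------------

def _static_ip(df: DFTensor, eps_o: np.ndarray, eps_v: np.ndarray,
               tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled OS/SS static blocks for the occupied singles space.

    S_ij = -1/2 sum_kab kernel_ij(k,a,b) [1/D_ik^ab + 1/D_jk^ab] with the
    opposite-spin kernel (ia|kb)(ja|kb) and the same-spin kernel
    (ia|kb)[(ja|kb) - (jb|ka)]; the diagonal reproduces the 2p1h part of the
    perturbative correction.
    """
    n_occ = df.n_occ
    t_os = np.zeros((n_occ, n_occ))
    t_ss = np.zeros((n_occ, n_occ))
    for k in range(n_occ):
        g = contract("iaQ,bQ->iab", df.j_ov, df.j_ov[k])  # (ia|kb)
        d = (eps_o[:, None, None] + eps_o[k]
             - eps_v[None, :, None] - eps_v[None, None, :])
        if np.abs(d).min() < tol:
            raise DegenerateReferenceError("vanishing 2p1h static denominator")
        u = g / d
        t_os += contract("iab,jab->ij", u, g)
        t_ss += contract("iab,jab->ij", u, g - np.swapaxes(g, 1, 2))
    return -0.5 * (t_os + t_os.T), -0.5 * (t_ss + t_ss.T)


def _static_ea(df: DFTensor, eps_o: np.ndarray, eps_v: np.ndarray,
               tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled OS/SS static blocks for the virtual singles space (2h1p fold)."""
    n_virt = df.n_virt
    t_os = np.zeros((n_virt, n_virt))
    t_ss = np.zeros((n_virt, n_virt))
    for c in range(n_virt):
        x = contract("iaQ,jQ->aij", df.j_ov, df.j_ov[:, c, :])  # (ai|cj)
        d = (eps_v[:, None, None] + eps_v[c]
             - eps_o[None, :, None] - eps_o[None, None, :])
        if np.abs(d).min() < tol:
            raise DegenerateReferenceError("vanishing 2h1p static denominator")
        u = x / d
        t_os += contract("aij,bij->ab", u, x)
        t_ss += contract("aij,bij->ab", u, x - np.swapaxes(x, 1, 2))
    return 0.5 * (t_os + t_os.T), 0.5 * (t_ss + t_ss.T)


def prepare_sigma_workspace(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    channel: str,
    scales: tuple[float, float],
    degeneracy_tol: float = DEGENERACY_TOL,
) -> SigmaWorkspace:
    """Build the per-channel workspace, including the one-off static blocks."""
    eps_occ = np.asarray(eps_occ, dtype=float)
    eps_virt = np.asarray(eps_virt, dtype=float)
    if channel == "ip":
        s_os, s_ss = _static_ip(df, eps_occ, eps_virt, degeneracy_tol)
    elif channel == "ea":
        s_os, s_ss = _static_ea(df, eps_occ, eps_virt, degeneracy_tol)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return SigmaWorkspace(
        channel=channel,
        df=df,
        eps_occ=eps_occ,
        eps_virt=eps_virt,
        scales=scales,
        static_os=s_os,
        static_ss=s_ss,
        degeneracy_tol=degeneracy_tol,
    )


# ----------------------------------------------------------------------------
# folded sigma builds
# ----------------------------------------------------------------------------

def _fold_ip(c: np.ndarray, omega: float, ws: SigmaWorkspace,
             scales: tuple[float, float], power: int = 1) -> np.ndarray:
    """Action of the folded 2h1p block U (w - D)^(-power) U^T on c."""
    df = ws.df
    c_os, c_ss = scales
    # M[k,l,a] = sum_j c_j (jk|al)
    half = contract("j,jkQ->kQ", c, df.j_oo)
    m = contract("kQ,laQ->kla", half, df.j_ov)
    den = (omega + ws.eps_occ[:, None, None] + ws.eps_occ[None, :, None]
           - ws.eps_virt[None, None, :])
    if np.abs(den).min() < ws.degeneracy_tol:
        raise DegenerateReferenceError(
            f"folded 2h1p denominator vanishes at omega={omega:.8f}"
        )
    w = ((c_os + c_ss) * m - c_ss * np.swapaxes(m, 0, 1)) / den**power
    r = contract("laQ,kla->kQ", df.j_ov, w)
    return contract("ikQ,kQ->i", df.j_oo, r)


def _fold_ea(c: np.ndarray, omega: float, ws: SigmaWorkspace,
             scales: tuple[float, float], power: int = 1) -> np.ndarray:
    """Action of the folded 2p1h block on c (virtual-virtual via slices only)."""
    df = ws.df
    c_os, c_ss = scales
    n_virt = df.n_virt
    # H[d,i,e] = sum_b c_b (bd|ie)
    h = np.empty((n_virt, df.n_occ, n_virt))
    for d in range(n_virt):
        u = contract("bQ,b->Q", df.j_vv_slice(d), c)
        h[d] = contract("Q,ieQ->ie", u, df.j_ov)
    den = (omega + ws.eps_occ[None, :, None]
           - ws.eps_virt[:, None, None] - ws.eps_virt[None, None, :])
    if np.abs(den).min() < ws.degeneracy_tol:
        raise DegenerateReferenceError(
            f"folded 2p1h denominator vanishes at omega={omega:.8f}"
        )
    w = ((c_os + c_ss) * h - c_ss * h.transpose(2, 1, 0)) / den**power
    out = np.zeros(n_virt)
    for d in range(n_virt):
        r = contract("ieQ,ie->Q", df.j_ov, w[d])
        out += contract("aQ,Q->a", df.j_vv_slice(d), r)
    return out


def sigma_ip(c: np.ndarray, omega: float, ws: SigmaWorkspace) -> np.ndarray:
    """sigma(c, w) for the ionization channel; linear in c at fixed w."""
    if ws.channel != "ip":
        raise ValueError("workspace was prepared for the attachment channel")
    c = np.asarray(c, dtype=float)
    out = -ws.eps_occ * c + ws.static @ c
    if ws.scales != (0.0, 0.0):
        out += _fold_ip(c, omega, ws, ws.scales)
    return out


def sigma_ea(c: np.ndarray, omega: float, ws: SigmaWorkspace) -> np.ndarray:
    """sigma(c, w) for the attachment channel."""
    if ws.channel != "ea":
        raise ValueError("workspace was prepared for the ionization channel")
    c = np.asarray(c, dtype=float)
    out = ws.eps_virt * c + ws.static @ c
    if ws.scales != (0.0, 0.0):
        out += _fold_ea(c, omega, ws, ws.scales)
    return out


def _sigma(c: np.ndarray, omega: float, ws: SigmaWorkspace) -> np.ndarray:
    return sigma_ip(c, omega, ws) if ws.channel == "ip" else sigma_ea(c, omega, ws)


# ----------------------------------------------------------------------------
# Davidson with maximum-overlap root following
# ----------------------------------------------------------------------------

def _orthonormalize(basis: list[np.ndarray], vec: np.ndarray,
                    tol: float = 1e-10) -> Optional[np.ndarray]:
    """Two-pass modified Gram-Schmidt in deterministic insertion order."""
    v = vec.copy()
    for _ in range(2):
        for b in basis:
            v -= (b @ v) * b
    norm = np.linalg.norm(v)
    if norm < tol:
        return None
    return v / norm


def _davidson(ws: SigmaWorkspace, omega: float, anchor: np.ndarray,
              resid_tol: float, max_subspace: int = MAX_SUBSPACE,
              collapse_to: int = COLLAPSE_TO,
              max_inner: int = 200) -> tuple[float, np.ndarray, float]:
    """Largest-overlap Ritz pair of the (symmetric) frozen-omega operator.

    Returns (theta, vector, residual_norm).  The followed root maximizes
    |<v, anchor>| among the Ritz vectors of each iteration.
    """
    n = ws.n_singles
    diag = ws.diag_first_order + np.diag(ws.static)
    basis: list[np.ndarray] = [anchor / np.linalg.norm(anchor)]
    sigmas: list[np.ndarray] = []
    for _ in range(max_inner):
        while len(sigmas) < len(basis):
            sigmas.append(_sigma(basis[len(sigmas)], omega, ws))
        V = np.column_stack(basis)
        S = np.column_stack(sigmas)
        H = V.T @ S
        H = 0.5 * (H + H.T)
        theta_all, y_all = np.linalg.eigh(H)
        ritz = V @ y_all  # full-space Ritz vectors, columns
        overlaps = np.abs(anchor @ ritz)
        pick = int(np.argmax(overlaps))
        theta = float(theta_all[pick])
        x = ritz[:, pick]
        r = S @ y_all[:, pick] - theta * x
        rnorm = float(np.linalg.norm(r))
        if rnorm <= resid_tol or len(basis) >= n:
            return theta, x / np.linalg.norm(x), rnorm
        if len(basis) >= max_subspace:
            # deterministic collapse: keep the followed root and the anchor
            basis = [x / np.linalg.norm(x)]
            extra = _orthonormalize(basis, anchor)
            if extra is not None and collapse_to > 1:
                basis.append(extra)
            sigmas = []
            continue
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-2, np.sign(denom + 1e-30) * 1e-2, denom)
        t = _orthonormalize(basis, r / denom)
        if t is None:
            t = _orthonormalize(basis, np.random.default_rng(len(basis)).standard_normal(n))
            if t is None:
                return theta, x / np.linalg.norm(x), rnorm
        basis.append(t)
    return theta, x / np.linalg.norm(x), rnorm


def solve_state(
    ws: SigmaWorkspace,
    target_orbital: int,
    conv_energy: float = CONV_ENERGY,
    max_iter: int = 50,
    resid_tol: float = RESID_TOL,
    overlap_floor: float = OVERLAP_FLOOR,
) -> IterativeState:
    """Self-consistent (omega, c) for the state dominated by ``target_orbital``.

    Macro-iterations freeze omega, run Davidson with maximum-overlap root
    following (anchored to the target unit vector, re-anchored to the
    previous iterate after the first pass), then update omega from the
    followed Ritz value; convergence requires |d omega| <= conv_energy and
    residual <= resid_tol.  A followed root whose anchor overlap drops below
    ``overlap_floor`` raises :class:`RootLostError`.
    """
    n = ws.n_singles
    if not (0 <= target_orbital < n):
        raise IndexError(f"target orbital {target_orbital} outside the "
                         f"{ws.channel} singles space of size {n}")
    anchor = np.zeros(n)
    anchor[target_orbital] = 1.0
    omega = float(ws.diag_first_order[target_orbital])
    theta, vec, rnorm = omega, anchor, 0.0
    converged = False
    iterations = 0
    for m in range(1, max_iter + 1):
        iterations = m
        theta, vec, rnorm = _davidson(ws, omega, anchor, resid_tol)
        if abs(anchor @ vec) < overlap_floor:
            raise RootLostError(
                f"{ws.channel} root for orbital {target_orbital} lost: "
                f"max anchor overlap {abs(anchor @ vec):.3f} < {overlap_floor}"
            )
        delta = theta - omega
        omega = theta
        anchor = vec.copy() if (anchor @ vec) >= 0 else -vec
        if abs(delta) <= conv_energy and rnorm <= resid_tol:
            converged = True
            break
    vec = vec / np.linalg.norm(vec)
    return IterativeState(
        channel=ws.channel,
        target_orbital=target_orbital,
        omega=omega,
        vector=vec,
        residual=rnorm,
        iterations=iterations,
        converged=converged,
    )


def pole_strength(state: IterativeState, ws: SigmaWorkspace) -> float:
    """Squared singles-block weight of the (normalized) full state vector.

    The doubles amplitudes of the folded solution are d = (wI - D)^(-1)
    U~^T c with the spin-scaled couplings, so ||d||^2 is the omega-derivative
    of the folded quadratic form and p = 1 / (1 + ||d||^2).  Exactly 1 when
    the second-order scales vanish.
    """
    if not state.converged:
        raise ValueError("pole strength requested for an unconverged state")
    if ws.scales == (0.0, 0.0):
        return 1.0
    fold = _fold_ip if ws.channel == "ip" else _fold_ea
    f2 = fold(state.vector, state.omega, ws, ws.scales, power=2)
    d2 = float(state.vector @ f2)
    return 1.0 / (1.0 + d2)


def second_order_expectations(
    state: IterativeState, ws: SigmaWorkspace
) -> tuple[float, float]:
    """Unscaled OS/SS second-order expectation values at the converged state.

    ``<c| S_spin + F_spin(omega) |c>`` per spin class; used for reporting the
    OS/SS composition of iterative results (the final energy additionally
    contains first-order singles relaxation, so these do not reassemble the
    total exactly unless the state is a pure Koopmans configuration).
    """
    fold = _fold_ip if ws.channel == "ip" else _fold_ea
    c = state.vector
    e_os = float(c @ (ws.static_os @ c) + c @ fold(c, state.omega, ws, (1.0, 0.0)))
    e_ss = float(c @ (ws.static_ss @ c) + c @ fold(c, state.omega, ws, (0.0, 1.0)))
    return e_os, e_ss
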