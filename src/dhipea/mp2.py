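"""Ground-state density-fitted MP2 with spin-component decomposition.

Closed-shell spatial-orbital MP2 on top of the factorized integrals: pair
amplitudes t_ij^ab = (ia|jb)/D_ij^ab with D_ij^ab = e_i + e_j - e_a - e_b,
the opposite-/same-spin split of the correlation energy

    E_os = sum_ijab (ia|jb)^2 / D_ij^ab
    E_ss = sum_ijab (ia|jb) [(ia|jb) - (ib|ja)] / D_ij^ab

and the Y intermediate (three-center integrals contracted with the spin-
scaled, antisymmetrized amplitudes) that the ionization/attachment
corrections reuse.  Amplitudes are never stored as a four-index object;
everything streams over occupied pairs.

A gapped reference is assumed: any pair denominator smaller in magnitude
than ``degeneracy_tol`` aborts with :class:`DegenerateReferenceError` rather
than level-shifting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .df_integrals import DFTensor, contract

__all__ = [
    "DegenerateReferenceError",
    "MP2Workspace",
    "pair_amplitudes",
    "mp2_energy",
    "build_Y",
    "prepare_mp2",
]

#: pairs closer to degeneracy than this (hartree) abort the calculation
DEGENERACY_TOL = 1e-8


class DegenerateReferenceError(RuntimeError):
    """Quasi-degenerate reference: a correlation denominator vanished."""


@dataclass
class MP2Workspace:
    """Per-reference MP2 data shared by the VIP/VEA corrections."""

    eps_occ: np.ndarray
    eps_virt: np.ndarray
    e_os: float
    e_ss: float
    e_scaled: float
    scales: tuple[float, float]
    y: Optional[np.ndarray] = None  # (n_occ, n_virt, n_aux_eff)


def pair_amplitudes(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    i: int,
    j: int,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> np.ndarray:
    """Doubles amplitude block t_ij^ab (n_virt x n_virt) for one occupied pair."""
    K = contract("aQ,bQ->ab", df.j_ov[i], df.j_ov[j])
    D = (eps_occ[i] + eps_occ[j]) - eps_virt[:, None] - eps_virt[None, :]
    if np.abs(D).min() < degeneracy_tol:
        raise DegenerateReferenceError(
            f"quasi-degenerate reference: |D_{i}{j}^ab| < {degeneracy_tol:g} E_h"
        )
    return K / D


def mp2_energy(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    scales: tuple[float, float] = (1.0, 1.0),
    degeneracy_tol: float = DEGENERACY_TOL,
) -> tuple[float, float, float]:
    """(E_os, E_ss, c_os*E_os + c_ss*E_ss) in hartree."""
    c_os, c_ss = scales
    e_os = 0.0
    e_ss = 0.0
    n_occ = df.n_occ
    for i in range(n_occ):
        for j in range(n_occ):
            K = contract("aQ,bQ->ab", df.j_ov[i], df.j_ov[j])
            D = (eps_occ[i] + eps_occ[j]) - eps_virt[:, None] - eps_virt[None, :]
            if np.abs(D).min() < degeneracy_tol:
                raise DegenerateReferenceError(
                    f"quasi-degenerate reference at pair ({i},{j})"
                )
            t = K / D
            e_os += float(np.sum(K * t))
            e_ss += float(np.sum((K - K.T) * t))
    return e_os, e_ss, c_os * e_os + c_ss * e_ss


def build_Y(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    scales: tuple[float, float] = (1.0, 1.0),
    degeneracy_tol: float = DEGENERACY_TOL,
) -> np.ndarray:
    """Spin-scaled Y intermediate, Y_ia^Q (n_occ, n_virt, n_aux_eff).

    Y_ia^Q = sum_jb [ (c_os + c_ss) t_ij^ab - c_ss t_ij^ba ] J_jb^Q, i.e. the
    opposite-spin part contracts the direct amplitudes and the same-spin part
    the antisymmetrized ones, each pre-multiplied by its scale; scales (1, 1)
    reproduce the unscaled definition 2 t - t^T.
    """
    c_os, c_ss = scales
    n_occ, n_virt, n_aux = df.j_ov.shape
    Y = np.zeros((n_occ, n_virt, n_aux))
    for i in range(n_occ):
        for j in range(n_occ):
            t = pair_amplitudes(df, eps_occ, eps_virt, i, j, degeneracy_tol)
            weighted = (c_os + c_ss) * t - c_ss * t.T
            Y[i] += contract("ab,bQ->aQ", weighted, df.j_ov[j])
    return Y


def prepare_mp2(
    df: DFTensor,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    scales: tuple[float, float] = (1.0, 1.0),
    with_y: bool = False,
) -> MP2Workspace:
    """Bundle the MP2 quantities one job needs into a workspace."""
    e_os, e_ss, e_scaled = mp2_energy(df, eps_occ, eps_virt, scales)
    y = build_Y(df, eps_occ, eps_virt, scales) if with_y else None
    return MP2Workspace(
        eps_occ=np.asarray(eps_occ, dtype=float),
        eps_virt=np.asarray(eps_virt, dtype=float),
        e_os=e_os,
        e_ss=e_ss,
        e_scaled=e_scaled,
        scales=scales,
        y=y,
    )
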