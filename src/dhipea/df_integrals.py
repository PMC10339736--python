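"""Density-fitted two-electron integrals in the MO basis, block-selectively.

The four-center repulsion integrals are factorized through an auxiliary basis
as K = J J^T with J = I V^(-1/2): ``build_metric_inverse_sqrt`` conditions the
two-center Coulomb metric by symmetric eigendecomposition (discarding
near-null directions), ``build_df_tensor`` half-transforms the three-center
integrals into the occupied-occupied and occupied-virtual MO blocks.  The
virtual-virtual block is *never* materialized: electron-attachment work gets
single-fixed-index slices on demand through :meth:`DFTensor.j_vv_slice`, and
ionization work needs no virtual-virtual integrals at all.

All hot contractions in this package go through :func:`contract`, a thin
``numpy.einsum`` wrapper that also accumulates a floating-point operation
estimate (product of the distinct index extents per contraction).  The
counter backs the empirical cost-scaling checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "contract",
    "reset_op_counter",
    "op_count",
    "DFTensor",
    "build_metric_inverse_sqrt",
    "build_df_tensor",
    "save_df_cache",
    "load_df_cache",
]


# ----------------------------------------------------------------------------
# instrumented contraction
# ----------------------------------------------------------------------------

_OP_COUNT: int = 0


def reset_op_counter() -> None:
    global _OP_COUNT
    _OP_COUNT = 0


def op_count() -> int:
    """Accumulated contraction cost estimate since the last reset."""
    return _OP_COUNT


def contract(subscripts: str, *operands: np.ndarray) -> np.ndarray:
    """``einsum`` with cost accounting.

    The cost of one contraction is estimated as the product of the extents of
    all distinct indices appearing in the subscript, the classic loop-nest
    bound for a single-term einsum.
    """
    global _OP_COUNT
    lhs = subscripts.split("->")[0]
    terms = lhs.split(",")
    sizes: dict[str, int] = {}
    for term, op in zip(terms, operands):
        for idx, dim in zip(term, np.shape(op)):
            sizes[idx] = dim
    cost = 1
    for dim in sizes.values():
        cost *= dim
    _OP_COUNT += cost
    return np.einsum(subscripts, *operands, optimize=False)


# ----------------------------------------------------------------------------
# metric conditioning
# ----------------------------------------------------------------------------

class MetricError(ValueError):
    """Ill-conditioned or invalid two-center Coulomb metric."""


def build_metric_inverse_sqrt(
    V: np.ndarray, drop_tol: float = 1e-10
) -> tuple[np.ndarray, int]:
    """Symmetric inverse square root of the auxiliary Coulomb metric.

    Returns ``(T, rank)`` with ``T`` of shape (n_aux, rank) satisfying
    ``T.T @ V @ T == I`` on the retained subspace.  Eigenvalues below
    ``drop_tol`` times the largest are discarded, guarding against linear
    dependence in the auxiliary basis.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise MetricError("metric must be a square matrix")
    if not (0.0 < drop_tol < 1.0):
        raise ValueError("drop_tol must lie in (0, 1)")
    asym = np.abs(V - V.T).max() if V.size else 0.0
    if asym > 1e-10 * max(1.0, np.abs(V).max()):
        raise MetricError(f"metric not symmetric (max asymmetry {asym:.3e})")
    w, U = np.linalg.eigh(0.5 * (V + V.T))
    keep = w > drop_tol * w.max()
    if not np.any(keep):
        raise MetricError("all metric eigenvalues dropped; metric is null")
    T = U[:, keep] / np.sqrt(w[keep])
    return T, int(keep.sum())


# ----------------------------------------------------------------------------
# MO-basis factor tensor
# ----------------------------------------------------------------------------

@dataclass
class DFTensor:
    """Blockwise J factors of K = J J^T in the active MO basis.

    The auxiliary index is the last (fastest-varying) storage dimension.
    ``j_vv_slice(b)`` returns the (n_virt, n_aux_eff) slice J[:, b, :] of the
    virtual-virtual block; every call is logged in ``vv_slice_log`` so tests
    can audit the access pattern.  No attribute ever holds the full
    virt x virt x aux array.
    """

    j_oo: np.ndarray  # (n_occ, n_occ, n_aux_eff)
    j_ov: np.ndarray  # (n_occ, n_virt, n_aux_eff)
    n_aux_effective: int
    _vv_provider: Optional[Callable[[int], np.ndarray]] = None
    vv_slice_log: list = field(default_factory=list)

    @property
    def n_occ(self) -> int:
        return self.j_ov.shape[0]

    @property
    def n_virt(self) -> int:
        return self.j_ov.shape[1]

    def j_vv_slice(self, b: int) -> np.ndarray:
        if self._vv_provider is None:
            raise RuntimeError(
                "virtual-virtual integrals were not requested for this tensor "
                "(IP-only build); rebuild with need_vv=True"
            )
        if not (0 <= b < self.n_virt):
            raise IndexError(f"virtual index {b} out of range")
        self.vv_slice_log.append(int(b))
        return self._vv_provider(int(b))


def build_df_tensor(
    ao_three_center: np.ndarray,
    mo_coefficients: np.ndarray,
    spaces: tuple[int, int, int],
    transform: np.ndarray,
    need_vv: bool = True,
) -> DFTensor:
    """Transform AO three-center integrals into blockwise MO J factors.

    ``spaces`` is (n_frozen_core, n_occupied_active, n_virtual); frozen
    orbitals are dropped entirely.  With ``need_vv=False`` (ionization
    workflows) even the half-transformed virtual intermediate needed for
    on-demand virtual-virtual slices is skipped.
    """
    I = np.asarray(ao_three_center, dtype=float)
    C = np.asarray(mo_coefficients, dtype=float)
    n_frozen, n_occ, n_virt = spaces
    if I.ndim != 3 or I.shape[0] != I.shape[1]:
        raise ValueError("three-center tensor must have shape (n_ao, n_ao, n_aux)")
    if C.shape[0] != I.shape[0]:
        raise ValueError("AO dimension mismatch between integrals and coefficients")
    if C.shape[1] != n_frozen + n_occ + n_virt:
        raise ValueError("MO coefficient columns do not match the space partition")
    if transform.shape[0] != I.shape[2]:
        raise ValueError("metric transform rows do not match the auxiliary basis")

    B = contract("mnP,PQ->mnQ", I, transform)
    C_o = C[:, n_frozen:n_frozen + n_occ]
    C_v = C[:, n_frozen + n_occ:]
    half_o = contract("mnQ,mi->inQ", B, C_o)
    j_oo = contract("inQ,nj->ijQ", half_o, C_o)
    j_ov = contract("inQ,na->iaQ", half_o, C_v)

    provider = None
    if need_vv:
        half_v = contract("mnQ,ma->anQ", B, C_v)

        def provider(b: int, _half=half_v, _C=C_v) -> np.ndarray:
            return contract("anQ,n->aQ", _half, np.ascontiguousarray(_C[:, b]))

    return DFTensor(
        j_oo=j_oo,
        j_ov=j_ov,
        n_aux_effective=transform.shape[1],
        _vv_provider=provider,
    )


# ----------------------------------------------------------------------------
# optional on-disk cache
# ----------------------------------------------------------------------------

def save_df_cache(df: DFTensor, path, key: str) -> None:
    """Store the materialized J blocks under ``key`` in an HDF5 container.

    The on-demand virtual-virtual provider is not persisted; a cached tensor
    reloads in IP-only form.  ``key`` should encode (geometry hash, basis,
    functional) so stale entries cannot be confused.
    """
    import h5py

    with h5py.File(path, "a") as fh:
        if key in fh:
            del fh[key]
        grp = fh.create_group(key)
        grp.create_dataset("j_oo", data=df.j_oo)
        grp.create_dataset("j_ov", data=df.j_ov)
        grp.attrs["n_aux_effective"] = df.n_aux_effective


def load_df_cache(path, key: str) -> DFTensor:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh[key]
        return DFTensor(
            j_oo=grp["j_oo"][()],
            j_ov=grp["j_ov"][()],
            n_aux_effective=int(grp.attrs["n_aux_effective"]),
        )
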