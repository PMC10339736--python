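"""Job configuration, geometry input, functional registry, and the SCF adapter.

This module owns everything that happens *before* correlated machinery runs:
parsing an XYZ geometry, resolving a density functional from the shipped
registry, partitioning the orbital spaces (frozen core / active occupied /
virtual), and the formal contract any self-consistent-field backend must
fulfil.  No exchange--correlation evaluation, integration grid, or SCF code
lives here: the backend delivers a converged closed-shell reference (MO
coefficients and orbital energies) together with raw AO-basis two- and
three-center Coulomb integrals, and everything downstream is functional-
agnostic apart from the second-order scaling factors.

Energies are held in hartree throughout; electronvolts appear only at the
reporting boundary via :data:`HARTREE_TO_EV` (CODATA 2018).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
import yaml

__all__ = [
    "HARTREE_TO_EV",
    "MoleculeSpec",
    "FunctionalConfig",
    "ReferenceState",
    "AOIntegralHandles",
    "ScfBackend",
    "load_geometry",
    "resolve_functional",
    "registry_names",
    "acquire_reference",
    "select_frozen_core",
]

#: hartree -> eV conversion, CODATA 2018.
HARTREE_TO_EV = 27.211386245988

# Element symbols, Z = 1..86.  Order defines the atomic number.
_ELEMENTS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe "
    "Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu "
    "Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn"
).split()
ATOMIC_NUMBER = {sym: z for z, sym in enumerate(_ELEMENTS, start=1)}


def _core_orbitals(z: int) -> int:
    """Number of chemically inert core *spatial* orbitals for element Z.

    Standard large-core convention: none for H/He, the 1s for Li--Ne,
    the Ne core for Na--Ar, the Ar core (+3d past Zn) for the fourth row,
    and so on.
    """
    if z <= 2:
        return 0
    if z <= 10:
        return 1
    if z <= 18:
        return 5
    if z <= 30:
        return 9
    if z <= 36:
        return 14
    if z <= 48:
        return 18
    if z <= 54:
        return 23
    if z <= 80:
        return 27  # Xe core + 4f
    return 39
    # (heavier elements are outside the artifact's tested envelope)


class GeometryError(ValueError):
    """Malformed XYZ input or inconsistent molecule specification."""


class FunctionalError(ValueError):
    """Unknown functional name or inconsistent functional definition."""


class BackendError(RuntimeError):
    """SCF backend failure (non-convergence, open-shell ground state, ...)."""


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeSpec:
    """A molecular geometry plus the basis names a backend needs.

    Coordinates are in angstrom.  Only closed-shell (singlet) references are
    supported by the correlated machinery, so ``spin_multiplicity`` must be 1.
    """

    atoms: tuple[tuple[str, float, float, float], ...]
    charge: int = 0
    spin_multiplicity: int = 1
    basis_name: str = ""
    aux_basis_name: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise GeometryError("molecule must contain at least one atom")
        for sym, *_ in self.atoms:
            if sym not in ATOMIC_NUMBER:
                raise GeometryError(f"unknown element symbol: {sym!r}")
        if self.spin_multiplicity != 1:
            raise GeometryError(
                "closed-shell reference required: spin multiplicity must be 1, "
                f"got {self.spin_multiplicity}"
            )

    @property
    def n_electrons(self) -> int:
        return sum(ATOMIC_NUMBER[sym] for sym, *_ in self.atoms) - self.charge


@dataclass(frozen=True)
class FunctionalConfig:
    """Parameters of an exchange--correlation functional relevant to this code.

    ``second_order_scales`` are the (opposite-spin, same-spin) weights applied
    to the second-order correction; a global single-parameter double hybrid is
    encoded as ``c_os == c_ss == alpha_C``.  Hybrid families carry (0, 0) and
    ``ansatz == "none"``: for them the reported VIP/VEA is the bare orbital
    energy (with sign per channel).
    """

    name: str
    family: str  # global_hybrid | lc_hybrid | global_DH | RS_DH | LC_DH
    alpha_x: float
    second_order_scales: tuple[float, float]
    ansatz: str  # cisd | adc2 | none
    n_empirical_params: int
    range_sep_param: Optional[float] = None
    exchange: str = ""
    correlation: str = ""
    citation: str = ""
    approximate: bool = False

    _FAMILIES = ("global_hybrid", "lc_hybrid", "global_DH", "RS_DH", "LC_DH")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise FunctionalError(f"unknown functional family: {self.family!r}")
        c_os, c_ss = self.second_order_scales
        if c_os < 0 or c_ss < 0:
            raise FunctionalError("second-order scales must be non-negative")
        if self.family in ("global_hybrid", "lc_hybrid"):
            if self.ansatz != "none" or self.second_order_scales != (0.0, 0.0):
                raise FunctionalError(
                    f"{self.name}: hybrid families define no second-order "
                    "machinery (ansatz must be 'none', scales (0, 0))"
                )

    @property
    def is_hybrid(self) -> bool:
        return self.family in ("global_hybrid", "lc_hybrid")


@dataclass(frozen=True)
class ReferenceState:
    """A converged closed-shell reference: the sole interface to DFT.

    Orbital energies are in hartree, ascending within the occupied and within
    the virtual block (ties keep backend order; see ``acquire_reference``).
    ``n_frozen_core`` leading occupied orbitals are excluded from the
    correlated space.
    """

    mo_coefficients: np.ndarray  # (n_ao, n_mo)
    orbital_energies: np.ndarray  # (n_mo,)
    n_frozen_core: int
    n_occupied_active: int
    n_virtual: int
    produced_by: FunctionalConfig

    def __post_init__(self) -> None:
        n_mo = self.n_frozen_core + self.n_occupied_active + self.n_virtual
        if self.orbital_energies.shape != (n_mo,):
            raise ValueError(
                "orbital energy count does not match the declared space "
                f"partition ({self.orbital_energies.shape[0]} vs {n_mo})"
            )
        if self.mo_coefficients.shape[1] != n_mo:
            raise ValueError("MO coefficient column count does not match spaces")
        if not np.all(np.isfinite(self.orbital_energies)):
            raise ValueError("orbital energies must be finite")
        n_occ = self.n_frozen_core + self.n_occupied_active
        eps_o = self.orbital_energies[:n_occ]
        eps_v = self.orbital_energies[n_occ:]
        if np.any(np.diff(eps_o) < -1e-12) or np.any(np.diff(eps_v) < -1e-12):
            raise ValueError("orbital energies must ascend within each block")
        if eps_o.size and eps_v.size and eps_o.max() > eps_v.min() + 1e-12:
            raise ValueError("occupied/virtual partition violates aufbau filling")

    @property
    def n_mo(self) -> int:
        return self.n_frozen_core + self.n_occupied_active + self.n_virtual

    @property
    def eps_occ(self) -> np.ndarray:
        """Active occupied orbital energies (frozen core excluded)."""
        lo = self.n_frozen_core
        return self.orbital_energies[lo:lo + self.n_occupied_active]

    @property
    def eps_virt(self) -> np.ndarray:
        return self.orbital_energies[self.n_frozen_core + self.n_occupied_active:]


@dataclass
class AOIntegralHandles:
    """Raw AO-basis Coulomb integrals delivered by the backend.

    ``three_center``  -- (n_ao, n_ao, n_aux) array of (mu nu | P) integrals
    ``two_center``    -- (n_aux, n_aux) Coulomb metric V_PQ
    ``attenuated_*``  -- optional range-attenuated analogues for RS-DH
                         correlation; ``None`` selects the full-range metric
                         (the default behaviour of this artifact).
    """

    three_center: np.ndarray
    two_center: np.ndarray
    attenuated_three_center: Optional[np.ndarray] = None
    attenuated_two_center: Optional[np.ndarray] = None


class ScfBackend(Protocol):
    """Adapter contract any SCF engine must satisfy.

    ``converge`` runs the closed-shell SCF for the given functional (exact-
    exchange fraction, range separation, scaled DFT correlation as the
    functional prescribes) and returns MO coefficients (n_ao, n_mo), orbital
    energies (n_mo, ascending), the number of doubly occupied orbitals, and
    the AO integral handles.  It raises :class:`BackendError` on SCF failure
    or if the ground state is open-shell.
    """

    def converge(
        self, mol: MoleculeSpec, func: FunctionalConfig
    ) -> tuple[np.ndarray, np.ndarray, int, AOIntegralHandles]:
        ...


# ----------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------

def load_geometry(path: str | Path, charge: int = 0,
                  spin_multiplicity: int = 1,
                  basis_name: str = "", aux_basis_name: str = "") -> MoleculeSpec:
    """Parse a standard XYZ file (count line, comment line, ``El x y z`` records)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GeometryError(f"{path}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path}: malformed atom count line: {lines[0]!r}") from exc
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != declared:
        raise GeometryError(
            f"{path}: atom count mismatch (declared {declared}, found {len(records)})"
        )
    atoms = []
    for ln in records:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: malformed atom record: {ln!r}")
        sym = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if sym not in ATOMIC_NUMBER:
            raise GeometryError(f"{path}: unknown element symbol: {parts[0]!r}")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError as exc:
            raise GeometryError(f"{path}: coordinate parse failure: {ln!r}") from exc
        atoms.append((sym, x, y, z))
    return MoleculeSpec(tuple(atoms), charge, spin_multiplicity,
                        basis_name, aux_basis_name)


def _load_registry() -> dict[str, FunctionalConfig]:
    from importlib.resources import files

    raw = yaml.safe_load(files("dhipea.data").joinpath(
        "functional_registry.yaml").read_text())
    registry: dict[str, FunctionalConfig] = {}
    for entry in raw["functionals"]:
        cfg = FunctionalConfig(
            name=entry["name"],
            family=entry["family"],
            alpha_x=float(entry["alpha_x"]),
            second_order_scales=(float(entry["c_os"]), float(entry["c_ss"])),
            ansatz=entry["ansatz"],
            n_empirical_params=int(entry["n_empirical_params"]),
            range_sep_param=(None if entry.get("omega") is None
                             else float(entry["omega"])),
            exchange=entry.get("exchange", ""),
            correlation=entry.get("correlation", ""),
            citation=entry.get("citation", ""),
            approximate=bool(entry.get("approximate", False)),
        )
        registry[cfg.name.lower()] = cfg
        for alias in entry.get("aliases", []) or []:
            registry.setdefault(alias.lower(), cfg)
    return registry


_REGISTRY_CACHE: Optional[dict[str, FunctionalConfig]] = None


def _registry() -> dict[str, FunctionalConfig]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = _load_registry()
    return _REGISTRY_CACHE


def registry_names() -> list[str]:
    """Canonical names of all registered functionals."""
    return list(dict.fromkeys(cfg.name for cfg in _registry().values()))


def resolve_functional(name: str) -> FunctionalConfig:
    """Look up a functional by (case-insensitive) name in the shipped registry."""
    reg = _registry()
    cfg = reg.get(name.lower())
    if cfg is None:
        avail = ", ".join(sorted(registry_names()))
        raise FunctionalError(f"unknown functional {name!r}; available: {avail}")
    return cfg


def select_frozen_core(mol: MoleculeSpec, policy: str | int = "auto") -> int:
    """Number of frozen occupied orbitals under the given policy.

    ``auto`` freezes the standard chemical core per element, ``none`` freezes
    nothing (all core electrons correlated), an integer freezes exactly that
    many lowest occupied orbitals.
    """
    n_occ = mol.n_electrons // 2
    if isinstance(policy, str) and policy == "auto":
        return sum(_core_orbitals(ATOMIC_NUMBER[sym]) for sym, *_ in mol.atoms)
    if isinstance(policy, str) and policy == "none":
        return 0
    try:
        n = int(policy)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unknown frozen-core policy: {policy!r}") from exc
    if n < 0 or n > n_occ:
        raise ValueError(
            f"explicit frozen-core count {n} outside [0, {n_occ}] "
            f"(only {n_occ} occupied orbitals)"
        )
    return n


def acquire_reference(
    mol: MoleculeSpec,
    func: FunctionalConfig,
    backend: ScfBackend,
    frozen_core: str | int = "auto",
) -> tuple[ReferenceState, AOIntegralHandles]:
    """Run the backend SCF and package the result as a :class:`ReferenceState`.

    The contract is validated before backend dispatch (closed shell, even
    electron count) and after (energy ordering, aufbau partition).  Degenerate
    orbital energies keep the backend-supplied index order (stable sort).
    """
    if mol.spin_multiplicity != 1:
        raise GeometryError("closed-shell reference required")
    if mol.n_electrons % 2 != 0:
        raise BackendError(
            f"odd electron count ({mol.n_electrons}): open-shell ground state"
        )
    mo_coeff, mo_energy, n_occ, handles = backend.converge(mol, func)
    mo_energy = np.asarray(mo_energy, dtype=float)
    # stable sort within each block; backend order breaks ties
    occ_order = np.argsort(mo_energy[:n_occ], kind="stable")
    virt_order = np.argsort(mo_energy[n_occ:], kind="stable") + n_occ
    order = np.concatenate([occ_order, virt_order])
    mo_energy = mo_energy[order]
    mo_coeff = np.asarray(mo_coeff, dtype=float)[:, order]
    n_frozen = select_frozen_core(mol, frozen_core)
    if n_frozen > n_occ:
        raise ValueError("frozen-core count exceeds occupied orbital count")
    ref = ReferenceState(
        mo_coefficients=mo_coeff,
        orbital_energies=mo_energy,
        n_frozen_core=n_frozen,
        n_occupied_active=n_occ - n_frozen,
        n_virtual=mo_energy.size - n_occ,
        produced_by=func,
    )
    return ref, handles
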