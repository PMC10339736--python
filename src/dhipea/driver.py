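"""Job orchestration: reference -> integrals -> states -> report.

A job is described by a flat key-value configuration (typically YAML):

    geometry:      path to an XYZ file (optional for the toy backend)
    functional:    registry name, or an inline mapping defining one
    basis, aux_basis:  basis names passed to the backend
    method:        orbital_energies | cisd | adc2
    channel:       ip | ea | both
    n_states:      states per channel (default 1)
    frozen_core:   auto | none | integer
    conv_energy:   iterative energy threshold in hartree (default 1e-6)
    max_iter:      macro-iteration cap for the iterative ansatz
    ea_sign:       attachment | ea  (reporting sign for the EA channel)
    second_order_scales: optional [c_os, c_ss] override
    backend:       "toy" (synthetic adapter) -- a real SCF engine can be
                   passed programmatically via run_job(backend=...)
    toy:           parameters for the synthetic backend

``orbital_energies`` reports bare first-order values (the hybrid-functional
shortcut), ``cisd`` adds the perturbative correction, ``adc2`` runs the
iterative folded solver.  Unconverged or lost states are reported with a
failure marker, never dropped.  Electronvolts appear only in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .adc2_ipea import (
    RootLostError,
    pole_strength,
    prepare_sigma_workspace,
    second_order_expectations,
    solve_state,
)
from .cisd_ipea import (
    apply_dh_scaling,
    first_order_states,
    vea_correction,
    vip_correction,
)
from .config_reference import (
    HARTREE_TO_EV,
    FunctionalConfig,
    ReferenceState,
    acquire_reference,
    load_geometry,
    resolve_functional,
    select_frozen_core,
)
from .df_integrals import build_df_tensor, build_metric_inverse_sqrt
from .fixtures import ToyScfBackend
from .mp2 import prepare_mp2

__all__ = ["JobReport", "run_job", "write_report"]

REPORT_SCHEMA_VERSION = 1
_TSV_COLUMNS = ("channel", "orbital", "omega1_eV", "corr_os_eV", "corr_ss_eV",
                "final_eV", "niter", "pole_strength")


@dataclass
class JobReport:
    provenance: dict
    states: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)


def _resolve_job_functional(spec) -> FunctionalConfig:
    if isinstance(spec, FunctionalConfig):
        return spec
    if isinstance(spec, str):
        return resolve_functional(spec)
    if isinstance(spec, dict):
        d = dict(spec)
        scales = (float(d.pop("c_os", 0.0)), float(d.pop("c_ss", 0.0)))
        return FunctionalConfig(
            name=d.pop("name"),
            family=d.pop("family"),
            alpha_x=float(d.pop("alpha_x", 1.0)),
            second_order_scales=scales,
            ansatz=d.pop("ansatz", "none"),
            n_empirical_params=int(d.pop("n_empirical_params", 0)),
            range_sep_param=d.pop("omega", None),
            citation=d.pop("citation", "inline definition"),
        )
    raise ValueError(f"cannot interpret functional specification: {spec!r}")


def _state_record(channel: str, orbital: int, omega1: float,
                  corr_os_scaled: float, corr_ss_scaled: float,
                  final: float, niter: int, pole, converged: bool,
                  residual: float, sign: float) -> dict:
    return {
        "channel": channel,
        "orbital": int(orbital),
        "omega1_eV": sign * omega1 * HARTREE_TO_EV,
        "corr_os_eV": sign * corr_os_scaled * HARTREE_TO_EV,
        "corr_ss_eV": sign * corr_ss_scaled * HARTREE_TO_EV,
        "final_eV": sign * final * HARTREE_TO_EV,
        "niter": int(niter),
        "pole_strength": None if pole is None else float(pole),
        "converged": bool(converged),
        "residual": float(residual),
    }


def run_job(config: dict | str | Path, backend=None) -> JobReport:
    """Execute one full job and return the structured report."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)

    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    func = _resolve_job_functional(cfg.get("functional", "toy"))
    method = cfg.get("method", "cisd")
    if method not in ("orbital_energies", "cisd", "adc2"):
        raise ValueError(f"unknown method {method!r}")
    channel = cfg.get("channel", "ip")
    if channel not in ("ip", "ea", "both"):
        raise ValueError(f"unknown channel {channel!r}")
    channels = ("ip", "ea") if channel == "both" else (channel,)
    n_states = int(cfg.get("n_states", 1))
    conv_energy = float(cfg.get("conv_energy", 1e-6))
    max_iter = int(cfg.get("max_iter", 50))
    ea_sign = cfg.get("ea_sign", "attachment")
    if ea_sign not in ("attachment", "ea"):
        raise ValueError(f"unknown ea_sign {ea_sign!r}")
    frozen_policy = cfg.get("frozen_core", "none")

    if method in ("cisd", "adc2") and func.is_hybrid:
        raise ValueError(
            f"{func.name}: hybrid functional defines no second-order "
            "correction; use method=orbital_energies"
        )
    scales = func.second_order_scales
    if "second_order_scales" in cfg:
        scales = tuple(float(s) for s in cfg["second_order_scales"])
        func = dataclasses.replace(func, second_order_scales=scales)

    # --- stage: reference -----------------------------------------------
    geometry_path = cfg.get("geometry")
    mol = None
    geometry_hash = "synthetic"
    if geometry_path is not None:
        mol = load_geometry(geometry_path,
                            charge=int(cfg.get("charge", 0)),
                            basis_name=cfg.get("basis", ""),
                            aux_basis_name=cfg.get("aux_basis", ""))
        geometry_hash = hashlib.sha256(
            Path(geometry_path).read_bytes()).hexdigest()[:16]
    if backend is None:
        if cfg.get("backend", "toy") != "toy":
            raise ValueError(
                f"no SCF backend available for backend={cfg.get('backend')!r}"
            )
        backend = ToyScfBackend(**cfg.get("toy", {}))
    if mol is not None:
        ref, handles = acquire_reference(mol, func, backend, frozen_policy)
    else:
        mo_coeff, mo_energy, n_occ, handles = backend.converge(None, func)
        n_frozen = 0 if frozen_policy in ("auto", "none") else int(frozen_policy)
        ref = ReferenceState(
            mo_coefficients=np.asarray(mo_coeff, dtype=float),
            orbital_energies=np.asarray(mo_energy, dtype=float),
            n_frozen_core=n_frozen,
            n_occupied_active=n_occ - n_frozen,
            n_virtual=len(mo_energy) - n_occ,
            produced_by=func,
        )
    timings["reference"] = time.perf_counter() - t0

    # --- stage: integrals --------------------------------------------------
    t1 = time.perf_counter()
    transform, _rank = build_metric_inverse_sqrt(handles.two_center)
    need_vv = "ea" in channels and method != "orbital_energies"
    df = build_df_tensor(
        handles.three_center, ref.mo_coefficients,
        (ref.n_frozen_core, ref.n_occupied_active, ref.n_virtual),
        transform, need_vv=need_vv,
    )
    timings["integrals"] = time.perf_counter() - t1

    c_os, c_ss = scales
    states: list[dict] = []
    for ch in channels:
        sign = -1.0 if (ch == "ea" and ea_sign == "ea") else 1.0
        t2 = time.perf_counter()
        firsts = first_order_states(ref, ch, n_states)
        if method == "orbital_energies":
            for orb, w1, _ in firsts:
                states.append(_state_record(ch, orb, w1, 0.0, 0.0, w1,
                                            0, None, True, 0.0, sign))
        elif method == "cisd":
            mp2ws = prepare_mp2(df, ref.eps_occ, ref.eps_virt, scales)
            for orb, w1, _ in firsts:
                corr = (vip_correction(df, mp2ws, orb) if ch == "ip"
                        else vea_correction(df, mp2ws, orb))
                res = apply_dh_scaling(w1, corr, func, ch, orb)
                states.append(_state_record(
                    ch, orb, w1, c_os * res.omega_D_os, c_ss * res.omega_D_ss,
                    res.omega_final, 0, res.pole_strength, True, 0.0, sign))
        else:  # adc2
            ws = prepare_sigma_workspace(df, ref.eps_occ, ref.eps_virt,
                                         ch, scales)
            for orb, w1, _ in firsts:
                try:
                    st = solve_state(ws, orb, conv_energy=conv_energy,
                                     max_iter=max_iter)
                except RootLostError:
                    states.append(_state_record(ch, orb, w1, float("nan"),
                                                float("nan"), float("nan"),
                                                max_iter, None, False,
                                                float("nan"), sign))
                    continue
                if st.converged:
                    pole = pole_strength(st, ws)
                    e_os, e_ss = second_order_expectations(st, ws)
                else:
                    pole, e_os, e_ss = None, float("nan"), float("nan")
                states.append(_state_record(
                    ch, orb, w1, c_os * e_os, c_ss * e_ss, st.omega,
                    st.iterations, pole, st.converged, st.residual, sign))
        timings[f"states_{ch}"] = time.perf_counter() - t2

    provenance = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "artifact_version": __version__,
        "geometry_hash": geometry_hash,
        "functional": func.name,
        "basis": cfg.get("basis", ""),
        "aux_basis": cfg.get("aux_basis", ""),
        "method": method,
        "channel": channel,
        "frozen_core": str(frozen_policy),
        "n_frozen_core": ref.n_frozen_core,
        "second_order_scales": [c_os, c_ss],
        "conv_energy": conv_energy,
        "ea_sign": ea_sign,
        "pole_strength_convention":
            "squared singles-block norm of the scaled unfolded state vector",
    }
    return JobReport(provenance=provenance, states=states, timings=timings)


def write_report(report: JobReport, format: str, path) -> None:
    """Serialize a report as schema-versioned JSON or fixed-column TSV."""
    path = Path(path)
    if format == "json":
        payload = {
            "provenance": report.provenance,
            "states": report.states,
            "timings": report.timings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for s in report.states:
            pole = s["pole_strength"]
            row = (
                s["channel"],
                str(s["orbital"]),
                f"{s['omega1_eV']:.4f}",
                f"{s['corr_os_eV']:.4f}",
                f"{s['corr_ss_eV']:.4f}",
                f"{s['final_eV']:.4f}",
                str(s["niter"]),
                "" if pole is None else f"{pole:.6f}",
            )
            marker = "" if s["converged"] else "\t# NOT CONVERGED"
            lines.append("\t".join(row) + marker)
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
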