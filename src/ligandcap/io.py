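"""CSV / YAML exchange formats.

Traces travel as two-column CSV (``t_s`` plus the signal column); datasets
carry a YAML sidecar with the generating ``truth`` record; solutions,
membranes, ligands and application protocols load from structured YAML
configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .capmeter import CapacitanceTrace
from .currents import CurrentTrace
from .electrostatics import IonSpecies, IonicSolution, MembraneSpec
from .kinetics import ApplicationProtocol, LigandSpec
from .synthetic import SyntheticDataset

__all__ = [
    "write_trace",
    "read_current_trace",
    "read_capacitance_trace",
    "write_dataset",
    "load_config",
    "solution_from_config",
    "membrane_from_config",
    "ligand_from_config",
    "protocol_from_config",
]


def write_trace(path: str | Path, trace: CurrentTrace | CapacitanceTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_current_trace(path: str | Path) -> CurrentTrace:
    df = pd.read_csv(path)
    return CurrentTrace(t=df["t_s"].to_numpy(), i=df["i_A"].to_numpy(), meta={"source": str(path)})


def read_capacitance_trace(path: str | Path) -> CapacitanceTrace:
    df = pd.read_csv(path)
    return CapacitanceTrace(
        t=df["t_s"].to_numpy(), c_m=df["c_m_F"].to_numpy(), meta={"source": str(path)}
    )


def _yaml_safe(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_dataset(out_dir: str | Path, dataset: SyntheticDataset, stem: str | None = None) -> None:
    """Write payload CSV plus a ``<stem>.truth.yaml`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or dataset.kind
    dataset.payload.to_csv(out / f"{stem}.csv", index=False)
    with open(out / f"{stem}.truth.yaml", "w") as fh:
        yaml.safe_dump({"kind": dataset.kind, "truth": _yaml_safe(dataset.truth)}, fh)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def solution_from_config(cfg: dict, side: str = "outer") -> IonicSolution:
    """Build a solution from ``{'ions': [{'name','valence','concentration_mM'}...]}``.

    mM equals mol·m⁻³, so the configured numbers are used as-is in SI.
    """
    return IonicSolution(
        (
            IonSpecies(d["name"], int(d["valence"]), float(d["concentration_mM"]))
            for d in cfg["ions"]
        ),
        side=side,
    )


def membrane_from_config(cfg: dict) -> MembraneSpec:
    """Keys: ``area_um2``, ``c_b_F_per_m2``, ``sigma_o_C_per_m2``, ``sigma_i_C_per_m2``."""
    return MembraneSpec(
        area=float(cfg["area_um2"]) * 1e-12,
        c_b=float(cfg.get("c_b_F_per_m2", 0.01)),
        sigma_o=float(cfg.get("sigma_o_C_per_m2", -0.005)),
        sigma_i=float(cfg.get("sigma_i_C_per_m2", -0.015)),
    )


def ligand_from_config(cfg: dict) -> LigandSpec:
    return LigandSpec(
        name=cfg["name"],
        k_on=float(cfg["k_on_per_M_s"]),
        k_off=float(cfg["k_off_per_s"]),
        z_lig=int(cfg.get("valence", 1)),
        pKa=cfg.get("pKa"),
        target_leaflet=cfg.get("target_leaflet", "outer"),
    )


def protocol_from_config(cfg: dict) -> ApplicationProtocol:
    """Keys: ``segments`` (list of ``[t_s, conc_M]``), ``k_exch_per_s``, ``pH_out``, ``pH_in``."""
    return ApplicationProtocol(
        [(float(t), float(c)) for t, c in cfg["segments"]],
        k_exch=float(cfg.get("k_exch_per_s", 20.0)),
        pH_out=float(cfg.get("pH_out", 7.4)),
        pH_in=float(cfg.get("pH_in", 7.2)),
    )
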