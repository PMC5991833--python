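"""Seeded generators for every dataset class the analysis pipeline consumes.

Each generator returns a :class:`SyntheticDataset` whose ``truth`` record
serialises the full generating parameters, so downstream fits can always be
checked for parameter recovery.  All randomness flows through one
``numpy.random.Generator`` derived from the :class:`NoiseModel` seed; the
same seed gives bit-identical output.

The default noise levels emulate the published recording statistics:
capacitance traces carry white Gaussian noise of SD 4.84 fF at 50 Hz; the
current-trace noise SD (0.5 pA after filtering) is a stand-in, since no
figure reports it.  Cell-to-cell variability is modelled as a log-normal
factor (SD 0.3) on the per-cell site count, motivated by the spread of the
reported saturating capacitance changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .capmeter import CircuitParams, StimulusProtocol, simulate_response
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .currents import iv_relation, simulate_current
from .electrostatics import IonicSolution, MembraneSpec, apparent_cm, delta_cm_for_adsorption
from .kinetics import (
    ApplicationProtocol,
    LigandSpec,
    SitePopulation,
    equilibrium_occupancy,
    k_app,
    occupancy_with_exchange,
)

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "gen_capacitance_trace",
    "gen_current_trace",
    "gen_concentration_response",
    "gen_iv_series",
    "gen_raw_squarewave",
]

#: log-normal SD of the per-cell site-count factor
CELL_SD = 0.3


@dataclass(frozen=True)
class NoiseModel:
    """Noise and reproducibility settings for the generators.

    ``current_noise_sd`` in A per sample (white, after filtering);
    ``cap_trace_noise_sd`` in F per 50 Hz capacitance sample; ``drift`` a
    linear baseline drift rate (trace units per second).
    """

    current_noise_sd: float = 0.5e-12
    cap_trace_noise_sd: float = 4.84e-15
    drift: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.current_noise_sd < 0 or self.cap_trace_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    kind: str
    payload: pd.DataFrame
    truth: dict = field(default_factory=dict)


def gen_capacitance_trace(
    protocol: ApplicationProtocol,
    ligand: LigandSpec,
    sites: SitePopulation,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    noise: NoiseModel,
    duration: float = 5.0,
    rate: float = 50.0,
    step: float = 0.04,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SyntheticDataset:
    """Capacitance time series under a ligand application/washout protocol.

    C_M(t) = baseline + ΔC_M_max·θ(t) + noise + drift·t, with θ(t) from the
    binding ODE under finite solution exchange and ΔC_M_max the model's
    apparent-capacitance change at full occupancy (noise is injected at the
    C_M level; see ``gen_raw_squarewave`` for the end-to-end alternative).
    """
    rng = noise.rng()
    occ = occupancy_with_exchange(protocol, ligand, t_end=duration, fs=rate)
    dsig = sites.delta_sigma_max(ligand, membrane)
    on_outer = ligand.target_leaflet == "outer"
    dcm_max = delta_cm_for_adsorption(
        membrane, dsig if on_outer else 0.0, 0.0 if on_outer else dsig, step, outer, inner, constants
    )
    baseline = apparent_cm(-step, step, membrane, outer, inner, constants)
    c_m = baseline + dcm_max * occ.theta
    c_m = c_m + noise.drift * occ.t + rng.normal(0.0, noise.cap_trace_noise_sd, occ.t.size)
    concs = sorted({c for _, c in protocol.segments if c > 0})
    truth = {
        "baseline_F": baseline,
        "delta_cm_max_F": dcm_max,
        "delta_sigma_max_C_per_m2": dsig,
        "k_app_per_s": {c: k_app(c, ligand) for c in concs},
        "ec50_M": ligand.kd,
        "seed": noise.seed,
    }
    payload = pd.DataFrame({"t_s": occ.t, "c_m_F": c_m, "theta": occ.theta})
    return SyntheticDataset(kind="capacitance_trace", payload=payload, truth=truth)


def gen_current_trace(
    concs: Sequence[float],
    ligand: LigandSpec,
    sites: SitePopulation,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    noise: NoiseModel,
    v_hold: float = 0.0,
    t_end: float = 1.0,
    fs: float = 10_000.0,
    mode: str = "closed_form",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SyntheticDataset:
    """Displacement-current traces for a concentration series (long format)."""
    rng = noise.rng()
    frames = []
    truth_k = {}
    truth_peak = {}
    for c in concs:
        tr = simulate_current(
            c, ligand, sites, membrane, outer, inner,
            v_hold=v_hold, t_end=t_end, fs=fs, mode=mode, constants=constants,
        )
        i = tr.i + rng.normal(0.0, noise.current_noise_sd, tr.i.size)
        frames.append(pd.DataFrame({"conc_M": c, "t_s": tr.t, "i_A": i}))
        truth_k[c] = k_app(c, ligand)
        truth_peak[c] = float(tr.i[np.argmax(np.abs(tr.i))])
    payload = pd.concat(frames, ignore_index=True)
    truth = {
        "k_on_per_M_s": ligand.k_on,
        "k_off_per_s": ligand.k_off,
        "k_app_per_s": truth_k,
        "peak_A": truth_peak,
        "seed": noise.seed,
    }
    return SyntheticDataset(kind="current_trace", payload=payload, truth=truth)


def gen_concentration_response(
    concs: Sequence[float],
    ligand: LigandSpec,
    noise_frac: float = 0.05,
    n_cells: int = 13,
    seed: int | None = None,
) -> SyntheticDataset:
    """Normalised concentration-response of the capacitance change.

    Per-cell normalised ΔC_M values scatter around the equilibrium-binding
    rectangular hyperbola c/(c + K_D) with Gaussian noise of SD
    ``noise_frac`` of the curve maximum (the per-cell amplitude factor
    cancels in the normalisation).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        for c in concs:
            y = equilibrium_occupancy(c, ligand) + rng.normal(0.0, noise_frac)
            rows.append({"cell": cell, "conc_M": c, "response_norm": y})
    payload = pd.DataFrame(rows)
    truth = {"ec50_M": ligand.kd, "max_norm": 1.0, "noise_frac": noise_frac, "seed": seed}
    return SyntheticDataset(kind="concentration_series", payload=payload, truth=truth)


def gen_iv_series(
    voltages: Sequence[float],
    conc: float,
    ligand: LigandSpec,
    sites: SitePopulation,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    noise_frac: float = 0.05,
    n_cells: int = 9,
    seed: int | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SyntheticDataset:
    """Per-cell normalised peak amplitudes versus holding potential.

    Each cell's amplitudes carry a log-normal scale factor (SD 0.3,
    removed again by the per-cell normalisation to the largest current)
    plus fractional Gaussian noise of SD ``noise_frac``.
    """
    rng = np.random.default_rng(seed)
    table, slope, _ = iv_relation(
        voltages, conc, ligand, sites, membrane, outer, inner, constants=constants
    )
    rows = []
    for cell in range(n_cells):
        factor = float(np.exp(rng.normal(0.0, CELL_SD)))
        peaks = table["peak_A"].to_numpy() * factor
        peaks = peaks * (1.0 + rng.normal(0.0, noise_frac, peaks.size))
        norm = peaks / np.max(np.abs(peaks))
        for v, p, nn in zip(table["v_mV"], peaks, norm):
            rows.append({"cell": cell, "v_mV": v, "peak_A": p, "normalized": nn})
    payload = pd.DataFrame(rows)
    truth = {"slope_per_mV": slope, "conc_M": conc, "seed": seed}
    return SyntheticDataset(kind="iv_series", payload=payload, truth=truth)


def gen_raw_squarewave(
    circuit: CircuitParams,
    protocol: StimulusProtocol,
    noise: NoiseModel,
    c_m_per_half: np.ndarray | None = None,
) -> SyntheticDataset:
    """Raw square-wave current trace feeding the capacitance estimator."""
    rng = noise.rng()
    tr = simulate_response(circuit, protocol, c_m_per_half=c_m_per_half)
    i = tr.i + rng.normal(0.0, noise.current_noise_sd, tr.i.size)
    payload = pd.DataFrame({"t_s": tr.t, "i_A": i})
    truth = {
        "r_s_Ohm": circuit.r_s,
        "r_m_Ohm": circuit.r_m,
        "c_m_F": circuit.c_m,
        "c_stray_F": circuit.c_stray,
        "seed": noise.seed,
    }
    if c_m_per_half is not None:
        truth["c_m_per_half_F"] = np.asarray(c_m_per_half, dtype=float)
    return SyntheticDataset(kind="raw_squarewave", payload=payload, truth=truth)
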