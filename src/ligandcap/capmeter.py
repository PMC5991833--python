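"""Whole-cell capacitance measurement by bipolar square-wave stimulation.

The cell is the standard whole-cell equivalent circuit: pipette access
resistance R_S in series with the membrane (R_M parallel C_M), plus a
stray/pipette capacitance charging with a fast time constant, and a
surface-charge battery V_Φ in series with C_M.  A train of ±40 mV, 200 Hz
square pulses elicits exponential current relaxations

    i(t) = I_ss + (I_inst − I_ss)·e^{−t/τ},   τ = C_M·R_S·R_M/(R_S + R_M)

per step; the relaxation parameters invert uniquely to (R_S, R_M, C_M).
V_Φ shifts only the DC charge on C_M and cancels from every step
difference, so the estimator is independent of it — which is exactly why
ligand adsorption shows up as an *apparent* capacitance change only
through the surface-potential nonlinearity, never through this circuit.

The stray capacitor charges within ~60 µs (six samples at 100 kHz); its
transient is excluded by discarding those samples after each step, which
renders the estimates insensitive to stray-capacitance changes.

Two estimation modes are provided.  ``exponential`` fits the bare
three-parameter relaxation and is exact on unfiltered records.  On records
low-pass filtered by the acquisition hardware (10 kHz Bessel), the filter's
group delay (~34 µs) biases the extrapolated step amplitude and with it
C_M by ~20%, so the default ``filtered_model`` mode fits the known-filter
model instead: the candidate circuit's ideal response is passed through the
same Bessel filter before comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.signal import bessel, lfilter, lfilter_zi

__all__ = [
    "CircuitParams",
    "StimulusProtocol",
    "EstimationResult",
    "CapacitanceTrace",
    "simulate_response",
    "estimate_params",
    "capacitance_timeseries",
]

from .currents import CurrentTrace


@dataclass(frozen=True)
class CircuitParams:
    """Whole-cell equivalent circuit.

    ``r_s`` series (access) resistance (Ω), ``r_m`` membrane resistance
    (Ω), ``c_m`` membrane capacitance (F), ``v_phi`` surface-charge battery
    (V; inert in this linear circuit, carried for bookkeeping), ``c_stray``
    stray/pipette capacitance (F) with charging time constant ``tau_stray``
    (s, default 10 µs so the transient completes within ~60 µs).
    """

    r_s: float = 5e6
    r_m: float = 500e6
    c_m: float = 30e-12
    v_phi: float = 0.0
    c_stray: float = 5e-12
    tau_stray: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.r_s > 0 and self.r_m > 0 and self.c_m > 0):
            raise ValueError("r_s, r_m, c_m must be positive")
        if self.c_stray < 0 or self.tau_stray <= 0:
            raise ValueError("c_stray must be >= 0 and tau_stray > 0")

    @property
    def tau(self) -> float:
        """Membrane charging time constant C_M·R_S·R_M/(R_S+R_M) (s)."""
        return self.c_m * self.r_s * self.r_m / (self.r_s + self.r_m)


@dataclass(frozen=True)
class StimulusProtocol:
    """Bipolar square-wave stimulus and acquisition settings.

    ±``amplitude`` square wave at ``frequency`` around ``v_hold``, sampled
    at ``f_sample`` and low-pass filtered at ``f_filter`` (4th-order Bessel,
    causal; ``None`` disables filtering).
    """

    amplitude: float = 0.040
    frequency: float = 200.0
    f_sample: float = 100_000.0
    f_filter: float | None = 10_000.0
    n_cycles: int = 10
    v_hold: float = 0.0

    def __post_init__(self) -> None:
        if self.f_filter is not None and not self.f_sample > 2 * self.f_filter:
            raise ValueError("f_sample must exceed twice the filter cutoff")
        if self.samples_per_half * 2 * self.frequency != self.f_sample:
            raise ValueError("f_sample must be an integer multiple of 2*frequency")
        if self.n_cycles < 1:
            raise ValueError("need at least one stimulus cycle")

    @property
    def samples_per_half(self) -> int:
        return int(round(self.f_sample / (2.0 * self.frequency)))

    @property
    def n_half(self) -> int:
        return 2 * self.n_cycles

    def levels(self) -> np.ndarray:
        """Applied potential per half-cycle: +amp, −amp, +amp, ... about v_hold."""
        signs = np.where(np.arange(self.n_half) % 2 == 0, 1.0, -1.0)
        return self.v_hold + self.amplitude * signs

    def bessel_ba(self) -> tuple[np.ndarray, np.ndarray]:
        if self.f_filter is None:
            raise ValueError("protocol has no filter")
        return bessel(4, self.f_filter, fs=self.f_sample, btype="low")


@dataclass(frozen=True)
class CapacitanceTrace:
    """Uniformly sampled capacitance estimate time series (F)."""

    t: np.ndarray
    c_m: np.ndarray
    r_s: np.ndarray | None = None
    r_m: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {"t_s": self.t, "c_m_F": self.c_m}
        if self.r_s is not None:
            d["r_s_Ohm"] = self.r_s
        if self.r_m is not None:
            d["r_m_Ohm"] = self.r_m
        return pd.DataFrame(d)


@dataclass
class EstimationResult:
    """Per-half-cycle circuit estimates and their trace-level summary.

    ``halfcycles`` holds one row per fitted relaxation (columns
    ``half_index, t_mid_s, r_s_Ohm, r_m_Ohm, c_m_F, rms_A``); excluded
    fits (residual RMS > 5× median) are dropped from the summary means.
    """

    halfcycles: pd.DataFrame
    mode: str
    n_excluded: int = 0

    @property
    def c_m_hat(self) -> float:
        return float(self.halfcycles["c_m_F"].mean())

    @property
    def r_s_hat(self) -> float:
        return float(self.halfcycles["r_s_Ohm"].mean())

    @property
    def r_m_hat(self) -> float:
        return float(self.halfcycles["r_m_Ohm"].mean())

    @property
    def c_m_sd(self) -> float:
        return float(self.halfcycles["c_m_F"].std(ddof=1)) if len(self.halfcycles) > 1 else 0.0

    def summary(self) -> str:
        h = self.halfcycles
        lines = [
            "Square-wave capacitance estimation",
            "==================================",
            f"mode: {self.mode}    relaxations used: {len(h)}    excluded: {self.n_excluded}",
            f"C_M = {self.c_m_hat * 1e12:10.4f} pF   (per-fit SD {self.c_m_sd * 1e15:.3f} fF)",
            f"R_S = {self.r_s_hat / 1e6:10.4f} MOhm",
            f"R_M = {self.r_m_hat / 1e6:10.2f} MOhm",
            f"residual RMS = {h['rms_A'].median() * 1e12:.4f} pA (median)",
        ]
        return "\n".join(lines)


def _ideal_response(
    circuit: CircuitParams,
    protocol: StimulusProtocol,
    c_m_per_half: np.ndarray | None = None,
) -> np.ndarray:
    """Unfiltered current response, exact piecewise-analytic evaluation."""
    sph = protocol.samples_per_half
    dt = 1.0 / protocol.f_sample
    levels = protocol.levels()
    rs, rm = circuit.r_s, circuit.r_m
    rsm = rs + rm
    tloc = np.arange(sph) * dt
    i = np.empty(protocol.n_half * sph)
    u = protocol.v_hold * rm / rsm  # membrane-node voltage, continuous across steps
    stray_amp = 0.0
    v_prev = protocol.v_hold
    stray_decay_half = math.exp(-sph * dt / circuit.tau_stray)
    for k, v in enumerate(levels):
        c_m = circuit.c_m if c_m_per_half is None else float(c_m_per_half[k])
        tau = c_m * rs * rm / rsm
        u_ss = v * rm / rsm
        decay = np.exp(-tloc / tau)
        u_t = u_ss + (u - u_ss) * decay
        seg = (v - u_t) / rs
        stray_amp = stray_amp * stray_decay_half + (v - v_prev) * circuit.c_stray / circuit.tau_stray
        seg = seg + stray_amp * np.exp(-tloc / circuit.tau_stray)
        i[k * sph : (k + 1) * sph] = seg
        u = u_ss + (u - u_ss) * math.exp(-sph * dt / tau)
        v_prev = v
        # stray amplitude remaining at the *next* step time
    return i


def simulate_response(
    circuit: CircuitParams,
    protocol: StimulusProtocol,
    c_m_per_half: np.ndarray | None = None,
) -> CurrentTrace:
    """Simulate the current response of the equivalent circuit to the stimulus.

    Per voltage step of size ΔV the membrane current jumps by ΔV/R_S and
    relaxes exponentially to the new steady state ΔV/(R_S+R_M); the stray
    transient rides on the first ~60 µs.  The trace is then low-pass
    filtered (causal Bessel) and returned at the protocol's sampling rate.
    ``c_m_per_half`` optionally imposes a slowly varying C_M (one value per
    half-cycle) for capacitance-tracking simulations.
    """
    if protocol.samples_per_half * 2 * protocol.frequency != protocol.f_sample:
        raise ValueError("sampling grid does not align with the square wave")
    tau_max = circuit.tau if c_m_per_half is None else float(np.max(c_m_per_half)) * (
        circuit.r_s * circuit.r_m / (circuit.r_s + circuit.r_m)
    )
    half_period = 1.0 / (2.0 * protocol.frequency)
    if half_period < 5.0 * tau_max:
        warnings.warn(
            f"half-period {half_period:.2e}s is not long against the circuit time constant "
            f"{tau_max:.2e}s; relaxations will not settle",
            stacklevel=2,
        )
    i = _ideal_response(circuit, protocol, c_m_per_half)
    if protocol.f_filter is not None:
        b, a = protocol.bessel_ba()
        i_hold = protocol.v_hold / (circuit.r_s + circuit.r_m)
        zi = lfilter_zi(b, a) * i_hold
        i, _ = lfilter(b, a, i, zi=zi)
    t = np.arange(i.size) / protocol.f_sample
    meta = {
        "protocol": protocol,
        "circuit": circuit,
        "filtered": protocol.f_filter is not None,
    }
    return CurrentTrace(t=t, i=i, meta=meta)


def _exp_seed(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Cheap (offset, amplitude, rate) seed for y = b + a·e^{−k·x}."""
    b0 = float(np.mean(y[-max(4, y.size // 10) :]))
    r = y - b0
    sign = 1.0 if r[0] >= 0 else -1.0
    good = sign * r > max(abs(r[0]) * 1e-6, 1e-18)
    if good.sum() < 3:
        return b0, float(r[0]), 1.0 / max(x[-1], 1e-9)
    slope, intercept = np.polyfit(x[good], np.log(sign * r[good]), 1)
    return b0, sign * math.exp(intercept), max(-slope, 1e-3)


def _fit_halfcycle_exponential(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Fit y = b + a·e^{−x/tau}; returns (a, b, tau, rms)."""
    b0, a0, k0 = _exp_seed(x, y)
    popt, _ = curve_fit(
        lambda xx, a, b, k: b + a * np.exp(-k * xx),
        x,
        y,
        p0=(a0, b0, k0),
        maxfev=20_000,
    )
    a, b, k = popt
    rms = float(np.sqrt(np.mean((y - (b + a * np.exp(-k * x))) ** 2)))
    return float(a), float(b), 1.0 / float(k), rms


def _invert_circuit(dv: float, jump: float, dss: float, tau: float) -> tuple[float, float, float]:
    """(R_S, R_M, C_M) from step size, instantaneous jump, steady-state change, tau."""
    r_s = dv / jump
    r_sm = dv / dss
    r_m = r_sm - r_s
    if r_m <= 0:
        raise RuntimeError("non-physical inversion: R_M <= 0")
    c_m = tau * r_sm / (r_s * r_m)
    return r_s, r_m, c_m


def estimate_params(
    trace: CurrentTrace,
    protocol: StimulusProtocol,
    mode: str = "auto",
    discard: int = 6,
    tau_stray: float = 1e-5,
) -> EstimationResult:
    """Estimate (R_S, R_M, C_M) from a square-wave current response.

    Per half-cycle the first ``discard`` samples after the step are dropped
    (stray-capacitor charging window) and the relaxation is fitted; the
    fitted (jump, steady-state, τ) triple inverts to the circuit values.
    The first half-cycle seeds the chain and yields no estimate.

    ``mode='exponential'`` fits the bare relaxation (exact on unfiltered
    input); ``mode='filtered_model'`` fits the candidate circuit's response
    passed through the protocol's Bessel filter and is the default whenever
    the trace was filtered (``mode='auto'``).
    """
    if mode == "auto":
        mode = "filtered_model" if protocol.f_filter is not None else "exponential"
    if mode not in ("exponential", "filtered_model"):
        raise ValueError(f"unknown estimation mode {mode!r}")
    sph = protocol.samples_per_half
    dt = 1.0 / protocol.f_sample
    levels = protocol.levels()
    n_half = min(protocol.n_half, trace.i.size // sph)
    if n_half < 2:
        raise ValueError("trace too short: need at least two half-cycles")
    x_fit = np.arange(discard, sph) * dt

    if mode == "filtered_model":
        b_f, a_f = protocol.bessel_ba()
        zi0 = lfilter_zi(b_f, a_f)
        t_full = np.arange(sph) * dt

    rows: list[dict] = []
    prev_fit: tuple[float, float, float] | None = None  # (a, b, tau) of previous half
    failures = 0
    for k in range(n_half):
        y_half = trace.i[k * sph : (k + 1) * sph]
        try:
            a, b, tau, rms = _fit_halfcycle_exponential(x_fit, y_half[discard:])
        except RuntimeError:
            warnings.warn(f"half-cycle {k}: exponential seed fit failed; skipped", stacklevel=2)
            prev_fit = None
            failures += 1
            continue

        if k == 0 or prev_fit is None:
            prev_fit = (a, b, tau)
            continue

        a_p, b_p, tau_p = prev_fit
        dv = levels[k] - levels[k - 1]
        half_period = sph * dt
        i_pre = b_p + a_p * math.exp(-half_period / tau_p)

        try:
            if mode == "exponential":
                r_s, r_m, c_m = _invert_circuit(dv, (a + b) - i_pre, b - b_p, tau)
            else:
                r_s0, r_m0, c_m0 = _invert_circuit(dv, (a + b) - i_pre, b - b_p, tau)
                v_cur, v_prev = levels[k], levels[k - 1]

                def model(p: np.ndarray) -> np.ndarray:
                    rs, rm, cm, astray = p
                    rsm = rs + rm
                    taum = cm * rs * rm / rsm
                    ipre = v_prev / rsm
                    iss = v_cur / rsm
                    iinst = ipre + dv / rs
                    x = iss + (iinst - iss) * np.exp(-t_full / taum)
                    x = x + astray * np.exp(-t_full / tau_stray)
                    out, _ = lfilter(b_f, a_f, x, zi=zi0 * ipre)
                    return out

                def resid(p: np.ndarray) -> np.ndarray:
                    return model(p)[discard:] - y_half[discard:]

                p0 = np.array([r_s0, r_m0, c_m0, dv * 5e-12 / tau_stray])
                sol = least_squares(
                    resid,
                    p0,
                    bounds=([1e3, 1e4, 1e-14, -np.inf], [1e10, 1e13, 1e-8, np.inf]),
                    x_scale=np.abs(
                        np.array([max(r_s0, 1e5), max(r_m0, 1e6), max(c_m0, 1e-13), max(abs(p0[3]), 1e-12)])
                    ),
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                    max_nfev=400,
                )
                r_s, r_m, c_m = sol.x[:3]
                rms = float(np.sqrt(np.mean(sol.fun**2)))
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"half-cycle {k}: inversion failed ({err}); skipped", stacklevel=2)
            prev_fit = (a, b, tau)
            failures += 1
            continue

        rows.append(
            {
                "half_index": k,
                "t_mid_s": (k + 0.5) * sph * dt,
                "r_s_Ohm": float(r_s),
                "r_m_Ohm": float(r_m),
                "c_m_F": float(c_m),
                "rms_A": rms,
            }
        )
        prev_fit = (a, b, tau)

    if not rows:
        raise RuntimeError("estimation failed on every half-cycle")
    df = pd.DataFrame(rows)
    med = df["rms_A"].median()
    keep = df["rms_A"] <= 5.0 * max(med, 1e-30)
    n_excluded = int((~keep).sum()) + failures
    return EstimationResult(halfcycles=df[keep].reset_index(drop=True), mode=mode, n_excluded=n_excluded)


def capacitance_timeseries(
    circuit: CircuitParams,
    protocol: StimulusProtocol,
    c_m_of_t: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None,
    out_rate: float = 50.0,
    current_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: str = "auto",
) -> CapacitanceTrace:
    """Track a slowly varying C_M(t) through the full measurement chain.

    Simulates the square-wave response with C_M imposed per half-cycle
    (quasi-static: the circuit parameters change slowly against the 200 Hz
    stimulus), optionally adds white current noise, estimates the circuit
    per half-cycle and block-averages the per-cycle estimates down to
    ``out_rate`` (default 200 Hz → 50 Hz, i.e. four cycles per point).
    """
    if protocol.frequency % out_rate != 0:
        raise ValueError("out_rate must divide the stimulus frequency")
    n_half = protocol.n_half
    sph = protocol.samples_per_half
    dt = 1.0 / protocol.f_sample
    if c_m_of_t is None:
        c_m_half = np.full(n_half, circuit.c_m)
    elif callable(c_m_of_t):
        t_mid = (np.arange(n_half) + 0.5) * sph * dt
        c_m_half = np.asarray(c_m_of_t(t_mid), dtype=float)
    else:
        c_m_half = np.asarray(c_m_of_t, dtype=float)
        if c_m_half.size != n_half:
            raise ValueError(f"need one C_M value per half-cycle ({n_half})")
    trace = simulate_response(circuit, protocol, c_m_per_half=c_m_half)
    i = trace.i
    if current_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        i = i + rng.normal(0.0, current_noise_sd, size=i.size)
        trace = CurrentTrace(t=trace.t, i=i, meta=trace.meta)
    est = estimate_params(trace, protocol, mode=mode)
    h = est.halfcycles
    cycle = (h["half_index"] // 2).to_numpy()
    per_cycle = h.groupby(cycle)[["c_m_F", "r_s_Ohm", "r_m_Ohm"]].mean()
    block = int(protocol.frequency / out_rate)
    grp = per_cycle.index.to_numpy() // block
    out = per_cycle.groupby(grp).mean()
    t_out = (out.index.to_numpy() + 0.5) * block / protocol.frequency
    return CapacitanceTrace(
        t=t_out,
        c_m=out["c_m_F"].to_numpy(),
        r_s=out["r_s_Ohm"].to_numpy(),
        r_m=out["r_m_Ohm"].to_numpy(),
        meta={"mode": est.mode, "n_excluded": est.n_excluded},
    )
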