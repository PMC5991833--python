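"""Ligand-site binding kinetics and the resulting surface-charge time course.

Pseudo-first-order binding of a charged ligand to a population of surface
sites:  dθ/dt = k_on·c(t)·(1−θ) − k_off·θ, with the local concentration
c(t) relaxing exponentially toward each application segment's target at the
solution-exchange rate of the perfusion device.  Bound ligand neutralises
fixed surface charge on its target leaflet, so the occupancy time course
maps linearly onto a surface-charge increment Δσ(t) = z·e·N·q·θ(t)/A.

Membrane-permeant weak bases additionally partition into the cell in their
neutral form (Henderson–Hasselbalch) and adsorb to the more negatively
charged inner leaflet; :func:`inner_accumulation` provides a first-order
phenomenological model for that slow inner-leaflet loading.

Ligand concentrations are in mol/L (M) to match the customary units of
k_on (M⁻¹·s⁻¹); everything electrostatic stays in SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import E_CHARGE
from .electrostatics import MembraneSpec

__all__ = [
    "LigandSpec",
    "SitePopulation",
    "ApplicationProtocol",
    "OccupancyTrace",
    "k_app",
    "equilibrium_occupancy",
    "occupancy_step",
    "occupancy_with_exchange",
    "surface_charge_timecourse",
    "neutral_fraction",
    "inner_accumulation",
]


@dataclass(frozen=True)
class LigandSpec:
    """A charged ligand: valence, association/dissociation rate constants,
    acid dissociation constant of the protonated form, and the membrane
    leaflet its binding sites face.

    ``k_on`` in M⁻¹·s⁻¹, ``k_off`` in s⁻¹; K_D = k_off/k_on.
    """

    name: str
    k_on: float
    k_off: float
    z_lig: int = 1
    pKa: float | None = None
    target_leaflet: str = "outer"

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError("k_on must be positive")
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")
        if self.target_leaflet not in ("outer", "inner"):
            raise ValueError("target_leaflet must be 'outer' or 'inner'")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant k_off/k_on (M)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class SitePopulation:
    """Binding sites per cell and surface charges neutralised per bound ligand."""

    n_sites: float = 2e7
    charges_per_site: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")

    def delta_sigma_max(self, ligand: LigandSpec, membrane: MembraneSpec) -> float:
        """Surface-charge increment at full occupancy, z·e·N·q/A (C·m⁻²)."""
        return (
            ligand.z_lig
            * E_CHARGE
            * self.n_sites
            * self.charges_per_site
            / membrane.area
        )


@dataclass(frozen=True)
class ApplicationProtocol:
    """Ligand application/washout schedule with finite solution exchange.

    ``segments`` is a sequence of (start time s, target concentration M)
    pairs with strictly increasing times; the local concentration relaxes
    exponentially toward each segment's target at rate ``k_exch`` (s⁻¹,
    ``math.inf`` = instantaneous exchange).
    """

    segments: tuple[tuple[float, float], ...]
    k_exch: float = 20.0
    pH_out: float = 7.4
    pH_in: float = 7.2

    def __init__(
        self,
        segments: Sequence[tuple[float, float]],
        k_exch: float = 20.0,
        pH_out: float = 7.4,
        pH_in: float = 7.2,
    ) -> None:
        segs = tuple((float(t), float(c)) for t, c in segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        times = [t for t, _ in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(c < 0 for _, c in segs):
            raise ValueError("concentrations must be >= 0")
        if not (k_exch > 0):
            raise ValueError("k_exch must be positive (use math.inf for instantaneous)")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "k_exch", float(k_exch))
        object.__setattr__(self, "pH_out", float(pH_out))
        object.__setattr__(self, "pH_in", float(pH_in))

    def concentration(self, t: np.ndarray) -> np.ndarray:
        """Local concentration c(t) (M), piecewise-exponential and continuous."""
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        c_start = 0.0  # before the first segment the chamber is ligand-free
        starts = [s for s, _ in self.segments]
        for k, (t0, target) in enumerate(self.segments):
            t1 = starts[k + 1] if k + 1 < len(starts) else math.inf
            mask = (t >= t0) & (t < t1)
            if math.isinf(self.k_exch):
                c[mask] = target
                c_start = target
            else:
                c[mask] = target + (c_start - target) * np.exp(-self.k_exch * (t[mask] - t0))
                if math.isfinite(t1):
                    c_start = target + (c_start - target) * math.exp(-self.k_exch * (t1 - t0))
        c[t < starts[0]] = 0.0
        return c


@dataclass(frozen=True)
class OccupancyTrace:
    """Fractional site occupancy and local ligand concentration on a time grid."""

    t: np.ndarray
    theta: np.ndarray
    c_local: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.theta) == len(self.c_local)):
            raise ValueError("t, theta, c_local must have equal length")


def k_app(conc: float, ligand: LigandSpec) -> float:
    """Apparent (pseudo-first-order) binding rate k_on·[L] + k_off  (s⁻¹)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return ligand.k_on * conc + ligand.k_off


def equilibrium_occupancy(conc: float, ligand: LigandSpec) -> float:
    """Equilibrium fractional occupancy c/(c + K_D); 1/2 at c = K_D."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0.0:
        return 0.0
    return conc / (conc + ligand.kd)


def occupancy_step(t: np.ndarray | float, conc: float, ligand: LigandSpec) -> np.ndarray | float:
    """Occupancy after an instantaneous concentration step at t = 0.

    θ(t) = θ_eq·(1 − e^{−k_app·t}), starting from zero occupancy.
    """
    rate = k_app(conc, ligand)
    theta_eq = equilibrium_occupancy(conc, ligand)
    return theta_eq * -np.expm1(-rate * np.asarray(t, dtype=float))


def occupancy_with_exchange(
    protocol: ApplicationProtocol,
    ligand: LigandSpec,
    t_end: float,
    fs: float = 1000.0,
    theta0: float = 0.0,
    rtol: float = 1e-8,
) -> OccupancyTrace:
    """Integrate dθ/dt = k_on·c(t)·(1−θ) − k_off·θ under finite exchange.

    ``c(t)`` is the protocol's piecewise-exponential concentration profile.
    Output on a uniform grid at ``fs`` Hz from 0 to ``t_end``.  Washout
    segments produce mono-exponential unbinding toward zero at rate → k_off
    once the chamber has cleared.
    """
    t_grid = np.arange(0.0, t_end, 1.0 / fs)
    if t_grid[-1] < t_end - 1e-12:
        t_grid = np.append(t_grid, t_end)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = float(protocol.concentration(np.array([t]))[0])
        return np.array([ligand.k_on * c * (1.0 - y[0]) - ligand.k_off * y[0]])

    # integrate segment-by-segment so the RHS is smooth within each solve
    boundaries = [s for s, _ in protocol.segments if 0.0 < s < t_end]
    edges = [0.0] + boundaries + [t_end]
    theta = np.empty_like(t_grid)
    y = theta0
    for a, b in zip(edges, edges[1:]):
        mask = (t_grid >= a) & (t_grid < b) if b < t_end else (t_grid >= a)
        eval_pts = t_grid[mask]
        # always evaluate the segment end so the state carries over exactly
        pad = not (eval_pts.size and eval_pts[-1] == b)
        sol = solve_ivp(
            rhs,
            (a, b),
            [y],
            method="LSODA",
            t_eval=np.append(eval_pts, b) if pad else eval_pts,
            rtol=rtol,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"occupancy integration failed: {sol.message}")
        if eval_pts.size:
            theta[mask] = sol.y[0, :-1] if pad else sol.y[0]
        y = float(sol.y[0, -1])
    theta = np.clip(theta, 0.0, 1.0)
    return OccupancyTrace(t=t_grid, theta=theta, c_local=protocol.concentration(t_grid))


def surface_charge_timecourse(
    occ: OccupancyTrace,
    sites: SitePopulation,
    ligand: LigandSpec,
    membrane: MembraneSpec,
) -> np.ndarray:
    """Surface-charge increment Δσ(t) = z·e·N·q·θ(t)/A on the target leaflet (C·m⁻²)."""
    return sites.delta_sigma_max(ligand, membrane) * occ.theta


def neutral_fraction(pH: float, ligand: LigandSpec) -> float:
    """Henderson–Hasselbalch fraction of the neutral (deprotonated) base,
    1/(1 + 10^(pKa − pH)); this is the membrane-permeant species."""
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    if ligand.pKa is None:
        raise ValueError(f"{ligand.name} has no pKa defined")
    return 1.0 / (1.0 + 10.0 ** (ligand.pKa - pH))


def inner_accumulation(
    protocol: ApplicationProtocol,
    ligand: LigandSpec,
    t_end: float,
    kappa_perm: float = 20.0,
    sigma_inner_max: float = 0.003,
    k_part: float = 30e-6,
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Slow inner-leaflet loading of a membrane-permeant weak base.

    Phenomenological first-order model: the inner-leaflet charge increment
    relaxes toward a saturable steady state

        Δσi_ss(c) = sigma_inner_max · c/(c + k_part)

    at rate ``kappa_perm · neutral_fraction(pH_out)``, i.e. permeation is
    carried by the neutral species only, so acidifying the bath suppresses
    loading by the Henderson–Hasselbalch factor (~80-fold for a pKa-10.2
    amine between pH 7.4 and pH 5.5).  Returns ``(t, delta_sigma_i)``.
    """
    if kappa_perm < 0 or sigma_inner_max < 0 or k_part <= 0:
        raise ValueError("kinetic parameters must be >= 0 (k_part > 0)")
    fn = neutral_fraction(protocol.pH_out, ligand)
    k_load = kappa_perm * fn
    t = np.arange(0.0, t_end, 1.0 / fs)
    if k_load == 0.0:
        return t, np.zeros_like(t)
    c = protocol.concentration(t)
    target = sigma_inner_max * c / (c + k_part)
    # exact exponential-Euler update for dσ/dt = k_load·(target(t) − σ)
    sigma = np.empty_like(t)
    sigma[0] = 0.0
    decay = math.exp(-k_load / fs)
    for n in range(1, t.size):
        sigma[n] = target[n - 1] + (sigma[n - 1] - target[n - 1]) * decay
    return t, sigma
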