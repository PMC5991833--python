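"""Planar Gouy-Chapman double-layer electrostatics of a charged membrane.

A membrane of specific capacitance ``c_b`` separates two electrolyte
solutions.  Each face carries a fixed surface charge density (phospholipid
head groups plus solvent-accessible protein residues).  Mobile ions screen
the faces, forming diffuse layers whose charge–potential relation is the
(multi-species) Grahame equation.  With the extracellular bulk grounded and
the intracellular bulk clamped to ``v_m``, charge balance on each face,

    outer:  sigma_o + c_b·(Φi − Φo) + sigma_d(Φo; outer solution)      = 0
    inner:  sigma_i − c_b·(Φi − Φo) + sigma_d(Φi − v_m; inner solution) = 0

determines the two surface potentials Φo and Φi, and with them the
transmembrane potential Φt = Φi − Φo.  Because Φt rather than v_m drops
across the membrane dielectric, surface-charge changes (e.g. adsorption of
a charged ligand) alter the capacitive charge Q = Φt·A·c_b and hence the
*apparent* membrane capacitance inferred from voltage steps.

Assumptions inherited from Gouy-Chapman theory: ions are point charges,
activity coefficients are unity, there is no Stern layer, and the geometry
is a planar two-plate stack (no lateral structure).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "IonSpecies",
    "IonicSolution",
    "MembraneSpec",
    "SurfacePotentials",
    "ConvergenceError",
    "diffuse_layer_charge",
    "diffuse_capacitance",
    "solve_surface_potentials",
    "capacitive_charge",
    "apparent_cm",
    "apparent_cm_level",
    "delta_cm_for_adsorption",
    "screening_scan",
]

_ELECTRONEUTRALITY_TOL = 1e-6
# exp() argument guard; |z·F·phi/RT| beyond this means a physically absurd input
_MAX_EXPONENT = 400.0


class ConvergenceError(RuntimeError):
    """Raised when the coupled charge-balance equations fail to converge."""


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species: ``z`` its integer valence, ``c_bulk`` its
    concentration far from the membrane (mol·m⁻³)."""

    name: str
    z: int
    c_bulk: float

    def __post_init__(self) -> None:
        if self.c_bulk < 0:
            raise ValueError(f"{self.name}: bulk concentration must be >= 0")
        if self.z == 0 and self.c_bulk > 0:
            raise ValueError(f"{self.name}: neutral species do not screen; omit them")


@dataclass(frozen=True)
class IonicSolution:
    """Electroneutral bulk electrolyte on one side of the membrane."""

    species: tuple[IonSpecies, ...]
    side: str = "outer"

    def __init__(self, species: Iterable[IonSpecies], side: str = "outer") -> None:
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "side", side)
        self._validate()

    def _validate(self) -> None:
        if self.side not in ("outer", "inner"):
            raise ValueError("side must be 'outer' or 'inner'")
        net = sum(s.z * s.c_bulk for s in self.species)
        gross = sum(abs(s.z) * s.c_bulk for s in self.species)
        if gross <= 0:
            raise ValueError("solution contains no charged species")
        if abs(net) / gross >= _ELECTRONEUTRALITY_TOL:
            raise ValueError(
                f"solution is not electroneutral: |sum z*c|/sum|z|*c = {abs(net) / gross:.3g}"
            )
        if not any(s.z > 0 and s.c_bulk > 0 for s in self.species):
            raise ValueError("solution needs at least one cation")
        if not any(s.z < 0 and s.c_bulk > 0 for s in self.species):
            raise ValueError("solution needs at least one anion")

    @property
    def ionic_strength(self) -> float:
        """(1/2)·Σ z²·c  (mol·m⁻³)."""
        return 0.5 * sum(s.z**2 * s.c_bulk for s in self.species)

    def kappa(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Debye parameter κ = sqrt(F²·Σ z²c / (εSol·R·T))  (m⁻¹)."""
        s2 = sum(s.z**2 * s.c_bulk for s in self.species)
        return math.sqrt(constants.F**2 * s2 / (constants.eps_sol * constants.RT))

    def scaled(self, factor: float) -> "IonicSolution":
        """Return a copy with every bulk concentration multiplied by ``factor``.

        Used for screening-strength scans: the diffuse-layer capacitance
        scales as sqrt(factor) in the linear regime.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return IonicSolution(
            (replace(s, c_bulk=s.c_bulk * factor) for s in self.species), side=self.side
        )


@dataclass(frozen=True)
class MembraneSpec:
    """Geometric and electrostatic description of the membrane.

    ``area`` in m²; ``c_b`` the specific membrane capacitance εb/δb in
    F·m⁻² (default 0.01 = 1 µF·cm⁻²); ``sigma_o``/``sigma_i`` the fixed
    outer/inner-leaflet surface charge densities in C·m⁻² (typically
    negative, the inner leaflet more so).
    """

    area: float
    c_b: float = 0.01
    sigma_o: float = -0.005
    sigma_i: float = -0.015

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("membrane area must be positive")
        if not self.c_b > 0:
            raise ValueError("specific capacitance c_b must be positive")
        for name in ("sigma_o", "sigma_i"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def geometric_capacitance(self) -> float:
        """A·c_b (F): the capacitance of the bare dielectric."""
        return self.area * self.c_b


@dataclass(frozen=True)
class SurfacePotentials:
    """Solution of the coupled charge-balance equations.

    ``phi_o``/``phi_i`` are the outer/inner surface potentials (V, relative
    to the grounded extracellular bulk), ``phi_t = phi_i - phi_o`` the
    transmembrane potential, ``v_m`` the applied bulk-to-bulk potential.
    ``residuals`` are the charge-balance residuals (C·m⁻²) at the solution.
    """

    phi_o: float
    phi_i: float
    v_m: float
    residuals: tuple[float, float] = (0.0, 0.0)

    @property
    def phi_t(self) -> float:
        return self.phi_i - self.phi_o


def _grahame_sum(phi: float, solution: IonicSolution, constants: PhysicalConstants) -> float:
    """Σ c_j·(exp(−z_j·F·φ/RT) − 1); the Boltzmann excess of the diffuse layer."""
    total = 0.0
    for s in solution.species:
        if s.c_bulk == 0.0:
            continue
        x = -s.z * constants.F * phi / constants.RT
        if abs(x) > _MAX_EXPONENT:
            raise OverflowError(
                f"surface potential {phi:.3g} V is outside the physically meaningful range"
            )
        total += s.c_bulk * math.expm1(x)
    return total


def diffuse_layer_charge(
    phi: float,
    solution: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Diffuse-layer charge per unit area screening a plane at potential ``phi``.

    Generalised Grahame relation

        sigma_d = −sign(phi) · sqrt( 2·εSol·R·T · Σ_j c_j∞·(e^{−z_j·F·phi/RT} − 1) )

    ``phi`` is the surface potential relative to the adjacent bulk (V).  The
    returned value is the net charge *in* the diffuse layer (C·m⁻²); it is
    opposite in sign to ``phi`` and odd in ``phi`` for a symmetric
    electrolyte.
    """
    if not math.isfinite(phi):
        raise ValueError("phi must be finite")
    if phi == 0.0:
        return 0.0
    s = _grahame_sum(phi, solution, constants)
    if s < 0.0:
        # The sum is non-negative for any electroneutral solution; a tiny
        # negative value can only be floating-point noise.
        gross = sum(sp.c_bulk for sp in solution.species)
        if s > -1e-12 * max(gross, 1.0):
            s = 0.0
        else:
            raise ConvergenceError(
                f"negative Grahame sum {s:.3g} for an electroneutral solution "
                "(internal consistency failure)"
            )
    return -math.copysign(math.sqrt(2.0 * constants.eps_sol * constants.RT * s), phi)


def diffuse_capacitance(
    phi: float,
    solution: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Differential diffuse-layer capacitance −d(sigma_d)/d(phi)  (F·m⁻²).

    At phi = 0 this is εSol·κ, the Debye-Hückel plate capacitance; it grows
    as the diffuse layer saturates at large |phi|.
    """
    if phi == 0.0:
        return constants.eps_sol * solution.kappa(constants)
    s = max(_grahame_sum(phi, solution, constants), 0.0)
    if s == 0.0:
        return constants.eps_sol * solution.kappa(constants)
    # d/dphi of sum = −(F/RT)·Σ c_j z_j e^{−z_j F phi/RT}
    dsum = 0.0
    for sp in solution.species:
        if sp.c_bulk == 0.0:
            continue
        x = -sp.z * constants.F * phi / constants.RT
        dsum += -sp.c_bulk * sp.z * constants.F / constants.RT * math.exp(x)
    sigma = math.copysign(math.sqrt(2.0 * constants.eps_sol * constants.RT * s), phi)
    # sigma_d = -sign(phi)*sqrt(2 eps RT s); d sigma_d/d phi = -eps RT dsum / sigma_signed
    return constants.eps_sol * constants.RT * dsum / sigma


def _linear_guess(
    v_m: float,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Initial guess from the linear three-capacitor (Debye-Hückel) circuit."""
    c_o = constants.eps_sol * outer.kappa(constants)
    c_i = constants.eps_sol * inner.kappa(constants)
    cb = membrane.c_b
    # c_o*po = sigma_o + cb*(pi-po);  c_i*(pi-vm) = sigma_i - cb*(pi-po)
    a = np.array([[c_o + cb, -cb], [cb, c_i + cb]])
    b = np.array([membrane.sigma_o, membrane.sigma_i + c_i * v_m])
    po, pi = np.linalg.solve(a, b)
    return float(po), float(pi)


def _bracketed_root(f, guess: float) -> float:
    """Root of a strictly decreasing scalar function by expanding bracket + brentq."""
    lo, hi = guess - 0.05, guess + 0.05
    width = 0.05
    for _ in range(60):
        if f(lo) > 0.0 and f(hi) < 0.0:
            return brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        width *= 2.0
        if f(lo) <= 0.0:
            lo -= width
        if f(hi) >= 0.0:
            hi += width
    raise ConvergenceError("could not bracket the per-face charge balance root")


def solve_surface_potentials(
    v_m: float,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SurfacePotentials:
    """Solve the coupled charge-balance equations for (Φo, Φi).

    The outer face is referenced to the grounded extracellular bulk, the
    inner face to the intracellular bulk clamped at ``v_m``.  The system is
    strictly monotone, so the solution is unique.  Solved by alternating
    bracketed per-face root refinement (each face's balance is strictly
    decreasing in its own potential) followed by a full Newton polish with
    the analytic Jacobian, to residuals at the floating-point floor.
    """
    cb = membrane.c_b
    so, si = membrane.sigma_o, membrane.sigma_i

    def f1(po: float, pi: float) -> float:
        return so + cb * (pi - po) + diffuse_layer_charge(po, outer, constants)

    def f2(po: float, pi: float) -> float:
        return si - cb * (pi - po) + diffuse_layer_charge(pi - v_m, inner, constants)

    po, pi = _linear_guess(v_m, membrane, outer, inner, constants)

    # Alternating per-face solves; the cross-coupling through c_b is weak
    # (c_b << diffuse-layer capacitance in all sensible regimes).
    for _ in range(200):
        po_new = _bracketed_root(lambda x: f1(x, pi), po)
        pi_new = _bracketed_root(lambda x: f2(po_new, x), pi)
        shift = max(abs(po_new - po), abs(pi_new - pi))
        po, pi = po_new, pi_new
        if shift < 1e-12:
            break

    # Newton polish in extended precision: float64 evaluation noise in the
    # charge sums otherwise dominates the residual at the converged point.
    po, pi, r1, r2 = _polish(po, pi, v_m, membrane, outer, inner, constants)
    scale = max(abs(so), abs(si), cb * 0.1)
    if max(abs(r1), abs(r2)) > 1e-12 * scale:
        raise ConvergenceError(
            f"charge balance did not converge: worst residual {max(abs(r1), abs(r2)):.3g} C/m^2 "
            f"(scale {scale:.3g})"
        )
    return SurfacePotentials(phi_o=po, phi_i=pi, v_m=v_m, residuals=(r1, r2))


def _polish(
    po: float,
    pi: float,
    v_m: float,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants,
) -> tuple[float, float, float, float]:
    """Extended-precision Newton refinement of the coupled balance.

    Runs a few Newton steps in ``numpy.longdouble`` and then returns the
    best float64-representable neighbour, with the residuals of that point
    evaluated in extended precision (i.e. the true residuals of the values
    actually returned).
    """
    ld = np.longdouble
    f = ld(constants.F)
    rt = ld(constants.R) * ld(constants.T)
    two_eps_rt = ld(2.0) * ld(constants.eps_sol) * rt
    cb = ld(membrane.c_b)
    so, si = ld(membrane.sigma_o), ld(membrane.sigma_i)
    vm = ld(v_m)
    zo = np.array([s.z for s in outer.species], dtype=ld)
    co = np.array([s.c_bulk for s in outer.species], dtype=ld)
    zi = np.array([s.z for s in inner.species], dtype=ld)
    ci = np.array([s.c_bulk for s in inner.species], dtype=ld)

    def sigma_d(phi, z, c):
        if phi == 0:
            return ld(0.0)
        s = np.sum(c * np.expm1(-z * f * phi / rt))
        s = max(s, ld(0.0))
        return -np.sign(phi) * np.sqrt(two_eps_rt * s)

    def cap_d(phi, z, c):
        s = np.sum(c * np.expm1(-z * f * phi / rt))
        if phi == 0 or s <= 0:
            return np.sqrt(f * f * np.sum(z * z * c) / (rt / ld(constants.eps_sol))) / ld(1.0)
        dsum = np.sum(-c * z * f / rt * np.exp(-z * f * phi / rt))
        sigma = np.sign(phi) * np.sqrt(two_eps_rt * s)
        return ld(constants.eps_sol) * rt * dsum / sigma

    def resid(p_o, p_i):
        r1 = so + cb * (p_i - p_o) + sigma_d(p_o, zo, co)
        r2 = si - cb * (p_i - p_o) + sigma_d(p_i - vm, zi, ci)
        return r1, r2

    x, y = ld(po), ld(pi)
    for _ in range(8):
        r1, r2 = resid(x, y)
        j11 = -cb - cap_d(x, zo, co)
        j22 = -cb - cap_d(y - vm, zi, ci)
        det = j11 * j22 - cb * cb
        dx = (-r1 * j22 + r2 * cb) / det
        dy = (-r2 * j11 + r1 * cb) / det
        x, y = x + dx, y + dy
        if abs(dx) < ld(1e-22) and abs(dy) < ld(1e-22):
            break

    # best float64 neighbour of the extended-precision root
    best = None
    for xo in (np.nextafter(float(x), -np.inf), float(x), np.nextafter(float(x), np.inf)):
        for yo in (np.nextafter(float(y), -np.inf), float(y), np.nextafter(float(y), np.inf)):
            r1, r2 = resid(ld(xo), ld(yo))
            m = max(abs(r1), abs(r2))
            if best is None or m < best[0]:
                best = (m, xo, yo, float(r1), float(r2))
    _, po, pi, r1, r2 = best
    return po, pi, r1, r2


def capacitive_charge(phi_t: float, membrane: MembraneSpec) -> float:
    """Total capacitive charge Q = Φt · A · c_b  (C)."""
    return phi_t * membrane.area * membrane.c_b


def apparent_cm(
    v_lo: float,
    v_hi: float,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Apparent membrane capacitance from a bipolar voltage step (F).

    The whole-cell measurement assumes the full applied step drops across
    the membrane; the model computes the charge actually moved,
    ΔQ = (Φt(v_hi) − Φt(v_lo))·A·c_b, and divides by the applied step:

        C_M_apparent = ΔQ / (v_hi − v_lo)

    With zero surface charges and strong screening nearly the whole step
    drops across the membrane and the result approaches A·c_b.
    """
    if v_hi == v_lo:
        raise ValueError("v_hi must differ from v_lo")
    hi = solve_surface_potentials(v_hi, membrane, outer, inner, constants)
    lo = solve_surface_potentials(v_lo, membrane, outer, inner, constants)
    dq = capacitive_charge(hi.phi_t, membrane) - capacitive_charge(lo.phi_t, membrane)
    return dq / (v_hi - v_lo)


def apparent_cm_level(
    v_m: float,
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Apparent C_M from the *total* capacitive charge at one level (F).

    C_M = Q/V_M = Φt(V_M)·A·c_b/V_M — the estimate a measurement makes when
    it assumes the whole applied potential drops across the membrane.
    Unlike :func:`apparent_cm` this retains the surface-potential offset
    (the V_Φ battery of the equivalent circuit) in the estimate, so it
    responds to ligand adsorption with opposite signs on the two leaflets:
    outer cation adsorption lowers it, inner cation accumulation raises it.
    """
    if v_m == 0.0:
        raise ValueError("v_m must be nonzero")
    sp = solve_surface_potentials(v_m, membrane, outer, inner, constants)
    return capacitive_charge(sp.phi_t, membrane) / v_m


def delta_cm_for_adsorption(
    membrane: MembraneSpec,
    delta_sigma_o: float,
    delta_sigma_i: float,
    step: float,
    outer: IonicSolution,
    inner: IonicSolution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    convention: str = "step",
) -> float:
    """Change in apparent C_M caused by surface-charge increments (F).

    ``delta_sigma_o``/``delta_sigma_i`` are added to the fixed charge of
    the respective leaflet (C·m⁻²; cation adsorption makes them positive)
    and the apparent capacitance is compared with the unperturbed membrane.

    ``convention='step'`` (default) uses the bipolar ±``step`` charge
    difference (:func:`apparent_cm`): the surface-potential offset cancels
    and the response is carried by the diffuse-layer nonlinearity.  Outer
    cation adsorption yields ΔC_M < 0 at the default parameter set; the
    inner-leaflet response is weaker and, because less negative fixed
    charge always relaxes the diffuse layer, also negative.

    ``convention='level'`` uses the single-level total-charge estimate
    (:func:`apparent_cm_level` at +``step``), which keeps the offset: there
    outer adsorption gives ΔC_M < 0 and inner cation accumulation
    ΔC_M > 0 — the convention in which the two leaflets are distinguishable
    by sign.
    """
    if convention == "step":
        def capp(m: MembraneSpec) -> float:
            return apparent_cm(-step, step, m, outer, inner, constants)
    elif convention == "level":
        def capp(m: MembraneSpec) -> float:
            return apparent_cm_level(step, m, outer, inner, constants)
    else:
        raise ValueError("convention must be 'step' or 'level'")
    perturbed = replace(
        membrane,
        sigma_o=membrane.sigma_o + delta_sigma_o,
        sigma_i=membrane.sigma_i + delta_sigma_i,
    )
    return capp(perturbed) - capp(membrane)


def screening_scan(
    scales: Sequence[float],
    membrane: MembraneSpec,
    outer: IonicSolution,
    inner: IonicSolution,
    delta_sigma_o: float = 0.0011,
    step: float = 0.04,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Sweep the screening strength and tabulate the model's responses.

    Every bulk concentration on both sides is multiplied by each value in
    ``scales``; for each condition the scan records the ligand-induced
    transmembrane-potential shift (``delta_phi_t_mV``, at v_m = 0, full
    charge increment ``delta_sigma_o``) and the apparent-capacitance change
    (``delta_cm_fF``, over a ±``step`` stimulus).  This documents how
    strongly both observables depend on the (experimentally uncertain)
    effective screening at the membrane surface.
    """
    rows = []
    for s in scales:
        o, i = outer.scaled(s), inner.scaled(s)
        base = solve_surface_potentials(0.0, membrane, o, i, constants)
        pert = solve_surface_potentials(
            0.0, replace(membrane, sigma_o=membrane.sigma_o + delta_sigma_o), o, i, constants
        )
        dphi = pert.phi_t - base.phi_t
        dcm = delta_cm_for_adsorption(membrane, delta_sigma_o, 0.0, step, o, i, constants)
        rows.append(
            {
                "scale": s,
                "delta_phi_t_mV": dphi * 1e3,
                "delta_cm_fF": dcm * 1e15,
                "kappa_outer_per_m": o.kappa(constants),
            }
        )
    return pd.DataFrame(rows)
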