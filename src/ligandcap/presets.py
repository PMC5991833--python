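"""Shipped parameter presets: recording solutions, ligands, membrane.

Solution compositions follow the standard whole-cell recording conditions
for HEK293 cells (concentrations in mM == mol·m⁻³; buffers, glucose and
EGTA are neutral at working pH and are excluded from the screening sums).

Two screening regimes are provided:

* ``standard_*`` — the recording solutions at face value.  These govern the
  true physiological screening (Debye length ~0.8 nm, diffuse-layer
  capacitance ~0.9 F·m⁻²), under which surface-charge perturbations are
  strongly shielded.
* ``reference_*`` — the dilute 1:1 screening condition used by the
  simulation figures and the sensitivity analysis: a symmetric monovalent
  electrolyte at the solutions' total salt concentration with the molar
  numeric value placed on the mol·m⁻³ scale (0.152 mol·m⁻³ outer,
  0.1554 mol·m⁻³ inner).  This reconstruction is calibrated to the
  reported ligand-induced transmembrane-potential shift of about −10 mV
  and simultaneously reproduces the reported saturating capacitance drop,
  current–voltage slope and minimal detectable expression density; see
  docs/methods.md for the rationale and a screening scan.

Default membrane: area chosen so that 2×10⁷ monovalent sites neutralised
at one charge each produce Δσ = +0.0011 C·m⁻² (the two published numbers
are mutually consistent only for A ≈ 2.912×10⁻⁹ m², ~29 pF at 1 µF·cm⁻²).
"""

from __future__ import annotations

from .constants import E_CHARGE
from .electrostatics import IonSpecies, IonicSolution, MembraneSpec
from .kinetics import LigandSpec, SitePopulation

__all__ = [
    "solution_preset",
    "ligand_preset",
    "default_membrane",
    "default_sites",
    "SOLUTION_PRESETS",
    "LIGAND_PRESETS",
]

#: number of binding sites per cell (saturation-binding estimate)
N_SITES_DEFAULT = 2e7
#: full-occupancy outer-leaflet charge increment (C·m⁻²)
DELTA_SIGMA_MAX = 0.0011
#: membrane area reconciling the two numbers above (m²)
AREA_DEFAULT = N_SITES_DEFAULT * E_CHARGE / DELTA_SIGMA_MAX  # ≈ 2.912e-9

#: screening scale of the reference simulation condition (see module docstring)
REFERENCE_SCREENING_SCALE = 1e-3


def _solution(side: str, comps: list[tuple[str, int, float]]) -> IonicSolution:
    return IonicSolution((IonSpecies(n, z, c) for n, z, c in comps), side=side)


def _std_bath() -> IonicSolution:
    # 140 NaCl, 3 KCl, 2.5 CaCl2, 2 MgCl2 (mM); HEPES/glucose neutral
    return _solution(
        "outer",
        [("Na+", 1, 140.0), ("K+", 1, 3.0), ("Ca2+", 2, 2.5), ("Mg2+", 2, 2.0), ("Cl-", -1, 152.0)],
    )


def _std_pipette() -> IonicSolution:
    # 152 NaCl, 1 CaCl2, 0.7 MgCl2 (mM); HEPES/EGTA neutral
    return _solution(
        "inner",
        [("Na+", 1, 152.0), ("Ca2+", 2, 1.0), ("Mg2+", 2, 0.7), ("Cl-", -1, 155.4)],
    )


def _nmdg_bath() -> IonicSolution:
    # Na+-free: NaCl replaced by NMDG-Cl
    return _solution(
        "outer",
        [("NMDG+", 1, 140.0), ("K+", 1, 3.0), ("Ca2+", 2, 2.5), ("Mg2+", 2, 2.0), ("Cl-", -1, 152.0)],
    )


def _mes_bath() -> IonicSolution:
    # Cl--free: NaCl replaced by Na-methanesulfonate
    return _solution(
        "outer",
        [("Na+", 1, 140.0), ("K+", 1, 3.0), ("Ca2+", 2, 2.5), ("Mg2+", 2, 2.0),
         ("MES-", -1, 140.0), ("Cl-", -1, 12.0)],
    )


def _reference_outer() -> IonicSolution:
    c = 152.0 * REFERENCE_SCREENING_SCALE
    return _solution("outer", [("cation", 1, c), ("anion", -1, c)])


def _reference_inner() -> IonicSolution:
    c = 155.4 * REFERENCE_SCREENING_SCALE
    return _solution("inner", [("cation", 1, c), ("anion", -1, c)])


SOLUTION_PRESETS = {
    "standard_bath": _std_bath,
    "standard_pipette": _std_pipette,
    "NMDG_bath": _nmdg_bath,
    "MES_bath": _mes_bath,
    "reference_outer": _reference_outer,
    "reference_inner": _reference_inner,
}


def solution_preset(name: str) -> IonicSolution:
    """Return a shipped solution preset by name (see ``SOLUTION_PRESETS``)."""
    try:
        return SOLUTION_PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown solution preset {name!r}; available: {sorted(SOLUTION_PRESETS)}")


# Ligand kinetics.  Cocaine: k_on from the published linear rate-concentration
# fit (2.9e5 M^-1 s^-1); k_off chosen so K_D equals the capacitance EC50 of
# 164 nM.  The other ligands' rate constants are not published; the presets
# carry order-of-magnitude stand-ins with the documented pKa values, adequate
# for the qualitative scenarios they serve (equilibrium, permeation).
LIGAND_PRESETS = {
    "cocaine": LigandSpec("cocaine", k_on=2.9e5, k_off=2.9e5 * 164e-9, z_lig=1, pKa=8.6),
    "serotonin": LigandSpec("serotonin", k_on=2.9e5, k_off=2.9e5 * 0.4e-6, z_lig=1, pKa=9.97),
    "desipramine": LigandSpec("desipramine", k_on=1e6, k_off=1e6 * 100e-9, z_lig=1, pKa=10.2),
    "ibogaine": LigandSpec("ibogaine", k_on=1e6, k_off=1e6 * 3e-6, z_lig=1, pKa=8.05),
}


def ligand_preset(name: str) -> LigandSpec:
    """Return a shipped ligand preset by name (see ``LIGAND_PRESETS``)."""
    try:
        return LIGAND_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown ligand preset {name!r}; available: {sorted(LIGAND_PRESETS)}")


def default_membrane() -> MembraneSpec:
    """Default cell membrane: ~29 pF, σo = −0.005 C·m⁻², σi = −0.015 C·m⁻²."""
    return MembraneSpec(area=AREA_DEFAULT, c_b=0.01, sigma_o=-0.005, sigma_i=-0.015)


def default_sites() -> SitePopulation:
    return SitePopulation(n_sites=N_SITES_DEFAULT, charges_per_site=1)
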