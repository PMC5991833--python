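"""Gouy-Chapman core: Grahame relation, coupled surface-potential solver,
capacitive charge and apparent-capacitance predictions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ligandcap as lc
from ligandcap.constants import DEFAULT_CONSTANTS

from conftest import conjugate, salt_1_1

C = DEFAULT_CONSTANTS


# ---------------------------------------------------------------------------
# diffuse_layer_charge


def test_zero_potential_zero_charge(salt150):
    assert lc.diffuse_layer_charge(0.0, salt150) == 0.0


@pytest.mark.parametrize("conc", [1.0, 10.0, 150.0, 500.0])
@pytest.mark.parametrize("phi", [-0.2, -0.05, -0.001, 0.001, 0.02, 0.15])
def test_grahame_matches_sinh_closed_form(conc, phi):
    """For a 1:1 electrolyte the multi-species Grahame sum reduces to the
    classical sinh form -sqrt(8 eps R T c) * sinh(F phi / 2RT)."""
    sol = salt_1_1(conc)
    got = lc.diffuse_layer_charge(phi, sol)
    expected = -math.sqrt(8 * C.eps_sol * C.RT * conc) * math.sinh(
        C.F * phi / (2 * C.RT)
    )
    assert got == pytest.approx(expected, rel=1e-12)


def test_grahame_odd_in_phi(salt150):
    for phi in (1e-4, 3e-3, 0.05, 0.2):
        assert lc.diffuse_layer_charge(-phi, salt150) == pytest.approx(
            -lc.diffuse_layer_charge(phi, salt150), rel=1e-12
        )


def test_debye_huckel_linearisation(salt150):
    """Small-potential limit: sigma_d -> -eps*kappa*phi within 1% at 1 mV."""
    phi = 1e-3
    kappa = salt150.kappa()
    got = lc.diffuse_layer_charge(phi, salt150)
    assert got == pytest.approx(-C.eps_sol * kappa * phi, rel=0.01)


def test_diffuse_capacitance_is_derivative(bath):
    h = 1e-8
    for phi in (-0.08, -0.01, 0.005, 0.06):
        num = -(
            lc.diffuse_layer_charge(phi + h, bath) - lc.diffuse_layer_charge(phi - h, bath)
        ) / (2 * h)
        assert lc.diffuse_capacitance(phi, bath) == pytest.approx(num, rel=1e-6)


def test_non_electroneutral_solution_rejected():
    with pytest.raises(ValueError, match="electroneutral"):
        lc.IonicSolution([lc.IonSpecies("Na+", 1, 100.0), lc.IonSpecies("Cl-", -1, 90.0)])


def test_solution_needs_both_ion_signs():
    with pytest.raises(ValueError):
        lc.IonicSolution([lc.IonSpecies("x", 1, 0.0), lc.IonSpecies("y", -1, 0.0)])


def test_neutral_species_with_concentration_rejected():
    with pytest.raises(ValueError, match="neutral"):
        lc.IonSpecies("glucose", 0, 20.0)


# ---------------------------------------------------------------------------
# solve_surface_potentials


def test_fully_symmetric_null_case(salt150):
    m = lc.MembraneSpec(area=3e-9, c_b=0.01, sigma_o=0.0, sigma_i=0.0)
    inner = salt_1_1(150.0, side="inner")
    sp = lc.solve_surface_potentials(0.0, m, salt150, inner)
    assert sp.phi_o == pytest.approx(0.0, abs=1e-15)
    assert sp.phi_i == pytest.approx(0.0, abs=1e-15)
    assert sp.phi_t == pytest.approx(0.0, abs=1e-15)


def test_phi_t_is_difference_by_construction(membrane, bath, pipette):
    sp = lc.solve_surface_potentials(-0.04, membrane, bath, pipette)
    assert sp.phi_t == sp.phi_i - sp.phi_o


def test_residual_contract_random_draws(rng):
    """Charge-balance residuals sit at the float64 floor: median below
    1e-15 and never above 1e-14 of the charge scale, over random draws."""
    rels = []
    for _ in range(300):
        c1 = rng.uniform(1, 300)
        c2 = rng.uniform(0, 20)
        outer = lc.IonicSolution(
            [
                lc.IonSpecies("m", 1, c1),
                lc.IonSpecies("d", 2, c2),
                lc.IonSpecies("a", -1, c1 + 2 * c2),
            ]
        )
        inner = salt_1_1(rng.uniform(1, 300), side="inner")
        m = lc.MembraneSpec(
            area=3e-9,
            c_b=rng.uniform(0.005, 0.02),
            sigma_o=rng.uniform(-0.03, 0.01),
            sigma_i=rng.uniform(-0.03, 0.01),
        )
        sp = lc.solve_surface_potentials(rng.uniform(-0.1, 0.1), m, outer, inner)
        scale = max(abs(m.sigma_o), abs(m.sigma_i), m.c_b * 0.1)
        rels.append(max(abs(r) for r in sp.residuals) / scale)
    assert np.median(rels) < 1e-15
    assert max(rels) < 1e-14


def test_global_charge_conjugation_antisymmetry(membrane, bath, pipette):
    """Negating both surface charges and v_m while flipping every ion valence
    negates all three potentials."""
    vm = 0.025
    sp = lc.solve_surface_potentials(vm, membrane, bath, pipette)
    m_neg = replace(membrane, sigma_o=-membrane.sigma_o, sigma_i=-membrane.sigma_i)
    sp_neg = lc.solve_surface_potentials(-vm, m_neg, conjugate(bath), conjugate(pipette))
    assert sp_neg.phi_o == pytest.approx(-sp.phi_o, rel=1e-10, abs=1e-15)
    assert sp_neg.phi_i == pytest.approx(-sp.phi_i, rel=1e-10, abs=1e-15)
    assert sp_neg.phi_t == pytest.approx(-sp.phi_t, rel=1e-10, abs=1e-15)


def test_phi_o_monotone_in_sigma_o(membrane, bath, pipette):
    sigmas = np.linspace(-0.02, 0.01, 7)
    phis = [
        lc.solve_surface_potentials(0.0, replace(membrane, sigma_o=s), bath, pipette).phi_o
        for s in sigmas
    ]
    assert np.all(np.diff(phis) > 0)


def test_phi_t_monotone_in_vm(membrane, bath, pipette):
    vms = np.linspace(-0.1, 0.1, 9)
    phits = [lc.solve_surface_potentials(v, membrane, bath, pipette).phi_t for v in vms]
    assert np.all(np.diff(phits) > 0)


def test_linear_response_matches_three_capacitor_circuit(rng):
    """For small charges and potentials the nonlinear solution matches the
    series (outer-diffuse, membrane, inner-diffuse) linear circuit to 2%."""
    for _ in range(20):
        outer = salt_1_1(rng.uniform(50, 300))
        inner = salt_1_1(rng.uniform(50, 300), side="inner")
        m = lc.MembraneSpec(
            area=3e-9,
            c_b=0.01,
            sigma_o=rng.uniform(-1e-4, 1e-4),
            sigma_i=rng.uniform(-1e-4, 1e-4),
        )
        vm = rng.uniform(-5e-3, 5e-3)
        sp = lc.solve_surface_potentials(vm, m, outer, inner)
        c_o = C.eps_sol * outer.kappa()
        c_i = C.eps_sol * inner.kappa()
        a = np.array([[c_o + m.c_b, -m.c_b], [m.c_b, c_i + m.c_b]])
        b = np.array([m.sigma_o, m.sigma_i + c_i * vm])
        po, pi = np.linalg.solve(a, b)
        assert sp.phi_o == pytest.approx(po, rel=0.02, abs=2e-6)
        assert sp.phi_i == pytest.approx(pi, rel=0.02, abs=2e-6)


def test_reference_condition_potential_shift(membrane, ref_outer, ref_inner):
    """Raising the outer charge by +0.0011 C/m^2 from -0.005 shifts the
    transmembrane potential by about -10 mV at the reference screening."""
    base = lc.solve_surface_potentials(0.0, membrane, ref_outer, ref_inner)
    pert = lc.solve_surface_potentials(
        0.0, replace(membrane, sigma_o=membrane.sigma_o + 0.0011), ref_outer, ref_inner
    )
    dphi = pert.phi_t - base.phi_t
    assert -0.012 < dphi < -0.007


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    sigma_o=st.floats(-0.02, 0.005),
    sigma_i=st.floats(-0.02, 0.005),
    vm=st.floats(-0.08, 0.08),
    conc=st.floats(5.0, 300.0),
)
def test_solver_always_satisfies_charge_balance(sigma_o, sigma_i, vm, conc):
    outer = salt_1_1(conc)
    inner = salt_1_1(conc, side="inner")
    m = lc.MembraneSpec(area=3e-9, c_b=0.01, sigma_o=sigma_o, sigma_i=sigma_i)
    sp = lc.solve_surface_potentials(vm, m, outer, inner)
    scale = max(abs(sigma_o), abs(sigma_i), 0.001)
    assert max(abs(r) for r in sp.residuals) < 1e-13 * scale


# ---------------------------------------------------------------------------
# capacitive charge and apparent capacitance


def test_capacitive_charge_arithmetic():
    m = lc.MembraneSpec(area=2.91e-9, c_b=0.01, sigma_o=0.0, sigma_i=0.0)
    assert lc.capacitive_charge(0.0, m) == 0.0
    assert lc.capacitive_charge(0.04, m) == pytest.approx(1.164e-12, rel=1e-12)
    big = replace(m, area=2 * m.area)
    assert lc.capacitive_charge(0.04, big) == pytest.approx(2 * 1.164e-12, rel=1e-12)


def test_apparent_cm_uncharged_membrane_physiological(bath, pipette):
    """With zero surface charge the apparent capacitance equals the
    three-capacitor series value, within ~2.5% of the bare A*c_b."""
    m = lc.MembraneSpec(area=2.912e-9, c_b=0.01, sigma_o=0.0, sigma_i=0.0)
    capp = lc.apparent_cm(-0.04, 0.04, m, bath, pipette)
    c_o = C.eps_sol * bath.kappa()
    c_i = C.eps_sol * pipette.kappa()
    series = m.geometric_capacitance / (1.0 + m.c_b / c_o + m.c_b / c_i)
    assert capp == pytest.approx(series, rel=2e-3)
    assert capp == pytest.approx(m.geometric_capacitance, rel=0.025)


def test_delta_cm_zero_increment_is_zero(membrane, ref_outer, ref_inner):
    assert (
        lc.delta_cm_for_adsorption(membrane, 0.0, 0.0, 0.04, ref_outer, ref_inner) == 0.0
    )


def test_delta_cm_outer_adsorption_reduces_capacitance(membrane, ref_outer, ref_inner):
    """Cation adsorption to the outer leaflet lowers the apparent C_M; at
    the reference condition the saturating drop is a few hundred fF."""
    dcm = lc.delta_cm_for_adsorption(membrane, 0.0011, 0.0, 0.04, ref_outer, ref_inner)
    assert dcm < 0
    assert -700e-15 < dcm < -200e-15


def test_delta_cm_sign_contract_level_convention(membrane, bath, pipette):
    """In the single-level (offset-retaining) estimate the two leaflets
    respond with opposite signs: outer cation adsorption lowers C_M, inner
    cation accumulation raises it."""
    outer = lc.delta_cm_for_adsorption(
        membrane, 0.0011, 0.0, 0.04, bath, pipette, convention="level"
    )
    inner = lc.delta_cm_for_adsorption(
        membrane, 0.0, 0.0011, 0.04, bath, pipette, convention="level"
    )
    assert outer < 0
    assert inner > 0


def test_delta_cm_linear_at_physiological_screening(membrane, bath, pipette):
    """|dC_M| is linear in |d sigma| within 5% up to 0.002 C/m^2 under
    full-strength screening."""
    base = lc.delta_cm_for_adsorption(membrane, 5e-4, 0.0, 0.04, bath, pipette) / 5e-4
    for dsig in (1e-3, 2e-3):
        slope = lc.delta_cm_for_adsorption(membrane, dsig, 0.0, 0.04, bath, pipette) / dsig
        assert slope == pytest.approx(base, rel=0.05)


def test_screening_scan_approaches_reported_shift(membrane, ref_outer, ref_inner):
    """Scanning the (monovalent) screening strength spans shifts from about
    -1 mV at full strength to the -10 mV dilute-screening asymptote."""
    scan = lc.screening_scan(
        [1e3, 1e2, 1e1, 1.0, 1e-1, 1e-2], membrane, ref_outer, ref_inner
    )
    shifts = scan["delta_phi_t_mV"].to_numpy()
    assert np.all(shifts < 0)
    assert np.all(np.diff(shifts) < 0)  # monotone with dilution
    assert shifts.max() > -1.5  # full-strength screening: ~-1.2 mV
    assert shifts.min() == pytest.approx(-10.0, rel=0.10)
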