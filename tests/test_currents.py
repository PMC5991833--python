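"""Displacement currents: potential-shift amplitude, closed-form and
exchange-limited simulation, decay fitting, current-voltage relation."""

from dataclasses import replace

import numpy as np
import pytest

import ligandcap as lc


@pytest.fixture
def condition(membrane, ref_outer, ref_inner, sites, cocaine):
    return dict(
        membrane=membrane, outer=ref_outer, inner=ref_inner, sites=sites, ligand=cocaine
    )


def _conjugate_ligand(ligand):
    return replace(ligand, z_lig=-ligand.z_lig)


# ---------------------------------------------------------------------------
# delta_phi_max


def test_no_sites_no_shift(condition):
    empty = lc.SitePopulation(n_sites=0)
    d = lc.delta_phi_max(
        condition["membrane"], condition["outer"], condition["inner"], empty, condition["ligand"]
    )
    assert d == 0.0


def test_full_occupancy_shift_matches_reported_scale(condition):
    """Saturating cation adsorption shifts the transmembrane potential by
    about -10 mV at the reference screening condition."""
    d = lc.delta_phi_max(
        condition["membrane"], condition["outer"], condition["inner"],
        condition["sites"], condition["ligand"],
    )
    assert d == pytest.approx(-10e-3, rel=0.3)


def test_shift_antisymmetric_under_charge_conjugation(condition):
    """Flipping every fixed charge, the ligand valence and every ion valence
    negates the potential shift."""
    from conftest import conjugate

    m = condition["membrane"]
    d = lc.delta_phi_max(
        m, condition["outer"], condition["inner"], condition["sites"], condition["ligand"]
    )
    m_neg = replace(m, sigma_o=-m.sigma_o, sigma_i=-m.sigma_i)
    d_neg = lc.delta_phi_max(
        m_neg,
        conjugate(condition["outer"]),
        conjugate(condition["inner"]),
        condition["sites"],
        _conjugate_ligand(condition["ligand"]),
    )
    assert d_neg == pytest.approx(-d, rel=1e-9)


# ---------------------------------------------------------------------------
# simulate_current


def test_zero_concentration_zero_current(condition):
    tr = lc.simulate_current(0.0, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"])
    assert np.all(tr.i == 0.0)


def test_cation_adsorption_current_is_inward(condition):
    tr = lc.simulate_current(100e-6, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"])
    assert tr.i[0] < 0  # peak at application onset, inward


def test_closed_form_matches_analytic_derivative(condition):
    """The simulated trace is C * dv/dt for v(t) = dphi_max*(1-e^{-k t})."""
    conc = 100e-6
    tr = lc.simulate_current(conc, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"],
                             t_end=0.5, fs=50_000.0)
    k = tr.meta["k_app_per_s"]
    c_tot = tr.meta["c_total_F"]
    dphi = tr.meta["delta_phi_max_V"]
    analytic = c_tot * dphi * k * np.exp(-k * tr.t)
    assert np.allclose(tr.i, analytic, rtol=1e-3)
    # and the numeric derivative of the occupancy ramp matches too
    v = dphi * (1.0 - np.exp(-k * tr.t))
    num = c_tot * np.gradient(v, tr.t)
    assert np.allclose(tr.i[1:-1], num[1:-1], rtol=2e-3)


def test_peak_amplitude_formula(condition):
    tr = lc.simulate_current(30e-6, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"])
    peak = tr.i[0]
    expected = tr.meta["c_total_F"] * tr.meta["delta_phi_max_V"] * tr.meta["k_app_per_s"]
    assert peak == pytest.approx(expected, rel=1e-12)


def test_charge_conservation(condition):
    """Integral of the displacement current equals C_total * dphi_max to 0.1%."""
    for conc in (10e-6, 100e-6, 300e-6):
        tr = lc.simulate_current(conc, condition["ligand"], condition["sites"],
                                 condition["membrane"], condition["outer"], condition["inner"],
                                 t_end=3.0, fs=10_000.0)
        q = np.trapezoid(tr.i, tr.t)
        expected = tr.meta["c_total_F"] * tr.meta["delta_phi_max_V"]
        assert q == pytest.approx(expected, rel=1e-3)


def test_concentration_series_ordering(condition):
    """Across 3-300 uM the peaks grow and the decays accelerate."""
    peaks, rates = [], []
    for conc in (3e-6, 10e-6, 30e-6, 100e-6, 300e-6):
        tr = lc.simulate_current(conc, condition["ligand"], condition["sites"],
                                 condition["membrane"], condition["outer"], condition["inner"])
        peaks.append(abs(tr.i[0]))
        rates.append(tr.meta["k_app_per_s"])
    assert np.all(np.diff(peaks) > 0)
    assert np.all(np.diff(rates) > 0)


def test_washout_charge_balances_application(condition):
    """With full equilibration, the charge moved during washout mirrors the
    application charge with opposite sign."""
    lig = condition["ligand"]
    prot = lc.ApplicationProtocol([(0.0, 100e-6), (3.0, 0.0)], k_exch=20.0)
    occ = lc.occupancy_with_exchange(prot, lig, t_end=200.0, fs=200)
    c_tot = condition["membrane"].geometric_capacitance
    dphi = lc.delta_phi_max(condition["membrane"], condition["outer"], condition["inner"],
                            condition["sites"], lig)
    dtheta = lig.k_on * occ.c_local * (1 - occ.theta) - lig.k_off * occ.theta
    i = c_tot * dphi * dtheta
    app = occ.t <= 3.0
    q_app = np.trapezoid(i[app], occ.t[app])
    q_wash = np.trapezoid(i[~app], occ.t[~app])
    assert q_wash == pytest.approx(-q_app, rel=5e-3)


def test_exchange_mode_peak_below_closed_form(condition):
    """Finite solution exchange caps the peak current at high concentration."""
    cf = lc.simulate_current(300e-6, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"])
    ex = lc.simulate_current(300e-6, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"],
                             mode="exchange", k_exch=20.0)
    assert np.max(np.abs(ex.i)) < np.max(np.abs(cf.i))


def test_exact_mode_close_to_factorised_mode(condition):
    """Re-solving the field at every instant stays within ~20% of the
    linear-response factorisation (the charge increment is not tiny)."""
    ex = lc.simulate_current(100e-6, condition["ligand"], condition["sites"],
                             condition["membrane"], condition["outer"], condition["inner"],
                             mode="exchange", k_exch=20.0, t_end=0.6, fs=200.0)
    exact = lc.simulate_current(100e-6, condition["ligand"], condition["sites"],
                                condition["membrane"], condition["outer"], condition["inner"],
                                mode="exact", k_exch=20.0, t_end=0.6, fs=200.0)
    q1 = np.trapezoid(ex.i, ex.t)
    q2 = np.trapezoid(exact.i, exact.t)
    assert q2 == pytest.approx(q1, rel=0.2)


# ---------------------------------------------------------------------------
# decay fitting and current-voltage relation


def test_fit_decay_rate_recovers_k_app(condition):
    for conc in (10e-6, 100e-6):
        tr = lc.simulate_current(conc, condition["ligand"], condition["sites"],
                                 condition["membrane"], condition["outer"], condition["inner"],
                                 t_end=2.0)
        rate, amp = lc.fit_decay_rate(tr)
        assert rate == pytest.approx(tr.meta["k_app_per_s"], rel=1e-6)
        assert amp == pytest.approx(tr.i[0], rel=1e-6)


def test_rate_regression_recovers_k_on(condition):
    """OLS of fitted decay rates on concentration recovers the generating
    k_on; the fitting chain is self-consistent to high precision."""
    concs = (3e-6, 10e-6, 30e-6, 100e-6, 300e-6)
    rates = []
    for conc in concs:
        tr = lc.simulate_current(conc, condition["ligand"], condition["sites"],
                                 condition["membrane"], condition["outer"], condition["inner"],
                                 t_end=2.0)
        rates.append(lc.fit_decay_rate(tr)[0])
    fit = lc.fit_rate_vs_conc(concs, rates)
    assert fit.params["k_on"] == pytest.approx(condition["ligand"].k_on, rel=1e-6)
    assert fit.params["k_off"] == pytest.approx(condition["ligand"].k_off, rel=1e-4)


def test_iv_relation_negative_slope(condition):
    voltages = np.arange(-50e-3, 31e-3, 10e-3)
    table, slope, se = lc.iv_relation(voltages, 100e-6, condition["ligand"],
                                      condition["sites"], condition["membrane"],
                                      condition["outer"], condition["inner"])
    assert slope < 0
    assert np.max(np.abs(table["normalized"])) == pytest.approx(1.0, rel=1e-12)
    # largest inward current at the most positive potential
    assert table["normalized"].iloc[-1] == pytest.approx(-1.0, rel=1e-12)


def test_iv_slope_sign_flips_with_ligand_valence(condition):
    voltages = np.arange(-50e-3, 31e-3, 10e-3)
    _, slope_pos, _ = lc.iv_relation(voltages, 100e-6, condition["ligand"],
                                     condition["sites"], condition["membrane"],
                                     condition["outer"], condition["inner"])
    anion = _conjugate_ligand(condition["ligand"])
    _, slope_neg, _ = lc.iv_relation(voltages, 100e-6, anion,
                                     condition["sites"], condition["membrane"],
                                     condition["outer"], condition["inner"])
    assert slope_pos < 0 < slope_neg


def test_iv_requires_three_voltages(condition):
    with pytest.raises(ValueError):
        lc.iv_relation([0.0, 0.01], 100e-6, condition["ligand"], condition["sites"],
                       condition["membrane"], condition["outer"], condition["inner"])
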