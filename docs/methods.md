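# Methods

This note records the model, its assumptions, the parameter choices that
matter, the synthetic-data design, and the numerical decisions — in enough
detail that every default can be traced and every limitation is explicit.

## 1. Electrostatic model

The membrane is a planar dielectric of specific capacitance c_b = εb/δb
between two semi-infinite electrolytes.  Each face carries a fixed surface
charge density (σₒ outer, σᵢ inner) arising from phospholipid head groups
and solvent-accessible protein residues.  Mobile ions screen each face,
and the diffuse-layer charge adjacent to a plane held at potential φ
relative to its bulk is the generalised Grahame relation

σ_d(φ) = −sign(φ)·√( 2 ε_sol R T Σⱼ c_j∞ (e^(−z_j F φ/RT) − 1) ).

With the extracellular bulk grounded and the intracellular bulk clamped at
V_M, charge balance on each face couples the two surface potentials:

- outer: σₒ + c_b (Φᵢ − Φₒ) + σ_d(Φₒ) = 0
- inner: σᵢ − c_b (Φᵢ − Φₒ) + σ_d(Φᵢ − V_M) = 0

The transmembrane potential is Φt = Φᵢ − Φₒ, the capacitive charge
Q = Φt·A·c_b, and the apparent capacitance of a measurement that assumes
the whole applied step drops across the membrane is ΔQ/ΔV_M.

Assumptions inherited from Gouy-Chapman theory: point-charge ions, unit
activity coefficients, no Stern layer, no ion-specific adsorption beyond
the explicit ligand term, planar geometry.  Buffer species (HEPES/MES,
glucose, EGTA) are treated as neutral at working pH and excluded from the
screening sums.

### Apparent-capacitance conventions

Two estimates are implemented, and the distinction matters:

- **step** (`apparent_cm`, default): C_M = ΔQ/ΔV over a bipolar ±step.
  Any static offset in Φt (the V_Φ battery of the equivalent circuit)
  cancels; the ligand response is carried entirely by the *nonlinearity*
  of the diffuse-layer capacitance.  In this convention adsorption of
  cations — which makes the fixed charge of either leaflet less negative
  and therefore *relaxes* the adjacent diffuse layer — lowers the apparent
  C_M on **both** leaflets; the outer response is much larger at the
  default charge asymmetry.
- **level** (`apparent_cm_level`): C_M = Q/V_M from the total charge at a
  single signed level.  The Φt offset survives, so the two leaflets are
  distinguishable by sign: outer cation adsorption lowers the estimate,
  inner cation accumulation raises it.  The biphasic
  decrease-then-increase seen with membrane-permeant amines emerges in
  this convention (the `inner-leaflet` report scenario uses it at
  full-strength screening, where it yields a ≈ −0.9 pF outer dip followed
  by a slow positive overshoot).

## 2. The reference screening condition

The magnitude of every ligand-induced observable is controlled by the
diffuse-layer capacitance C_dl = dσ_d/dφ of the outer solution.  At the
full-strength recording solutions (≈150 mM salt, C_dl ≈ 0.9 F·m⁻²) the
model yields a full-occupancy potential shift of −1.2 mV, a step-mode
capacitance change of ≈ −1 fF and a minimal detectable density of ~5×10⁶
units/pF: physiological screening almost completely shields surface-charge
perturbations from a bipolar capacitance measurement.

The simulation results this package emulates were however computed, in
the original work, at a far weaker screening level whose exact inputs were
never published.  We reconstruct that operating point as a
symmetric 1:1 electrolyte at the recording solutions' total salt
concentration with the **molar numeric value placed on the mol·m⁻³ scale**
(0.152 mol·m⁻³ outer, 0.1554 inner; a mol/L-for-mol/m³ unit slip is the
most parsimonious reading).  This single choice — calibrated against the
reported −10 mV full-occupancy potential shift and fixed before any other
quantity was examined — simultaneously reproduces all four published
simulation outputs:

| quantity (defaults, Δσ = +0.0011 C·m⁻²) | this model | reported |
|---|---|---|
| full-occupancy ΔΦt | −9.55 mV | ≈ −10 mV |
| saturating ΔC_M (±40 mV) | −423 fF | ≈ −500 fF |
| normalised I–V slope | −1.41×10⁻³/mV | −1.1×10⁻³/mV |
| minimal density (2×4.84 fF) | 18,329 units/pF | ≈ 20,000 units/pF |

`screening_scan` documents the whole family: the shift grows monotonically
from −1.2 mV (full strength) toward a dilute-screening **asymptote of
−9.89 mV** — the membrane capacitor couples the faces and caps the shift
at (2RT/F)·ln-type growth; "about −10 mV" is exactly this asymptote.
Scans retaining the divalent Ca²⁺/Mg²⁺ plateau lower (−6.9 mV), because
z = 2 ions dominate screening at large |Φₒ|; the reference condition is
therefore monovalent.  Users studying real physiological conditions should
use the `standard_bath`/`standard_pipette` presets and expect the fF-scale
responses above.

## 3. Membrane, sites and ligand defaults

- Site count N = 2×10⁷ per cell and full-occupancy charge increment
  Δσ = +0.0011 C·m⁻² are both published; they are mutually consistent only
  for A = N·e/Δσ = 2.912×10⁻⁹ m² (29.1 pF at c_b = 0.01 F·m⁻²), which is
  the default area.
- σₒ = −0.005 C·m⁻² (measured for untransfected HEK293 cells);
  σᵢ = −0.015 C·m⁻² is a configurable default — only "inner leaflet more
  negative" is documented; the solved observables depend on it weakly.
- Temperature 295 K; ε_sol = 78.5 ε₀.
- Cocaine: k_on = 2.9×10⁵ M⁻¹s⁻¹ (slope of the measured rate–concentration
  line); k_off = k_on × 164 nM = 0.0476 s⁻¹ so that K_D equals the
  capacitance-derived EC50.  (The competing printed EC50 of 156 nM is noted
  in the preset comments; the legend value is used.)  Serotonin,
  desipramine and ibogaine presets carry the documented pKa values (9.97,
  10.2, 8.05) and order-of-magnitude stand-in rate constants, adequate for
  the equilibrium and permeation scenarios they serve — no rate constants
  for these ligands are published.

## 4. Binding kinetics and solution exchange

Occupancy follows θ̇ = k_on·c(t)·(1−θ) − k_off·θ with the chamber
concentration relaxing exponentially toward each protocol segment's target
at the solution-exchange rate k_exch (default 20 s⁻¹, the speed of a
multi-tube perfusion device; `math.inf` gives instantaneous steps and the
closed form θ_eq·(1−e^(−k_app t))).  Above ≈30 µM the exchange, not
binding, limits the observed rise rate — the `rate-saturation` scenario
reproduces the corrected-rate curve.  Integration: LSODA, rtol 10⁻⁸,
atol 10⁻¹², segment-by-segment so the right-hand side stays smooth, state
carried across boundaries exactly; θ clipped to [0, 1] against roundoff.

Inner-leaflet accumulation of membrane-permeant weak bases is a
phenomenological stand-in (no governing equation is published): Δσᵢ relaxes
at rate κ_perm·(neutral fraction) toward a saturable target
σ_max·c/(c+K_part).  Defaults κ_perm = 20 s⁻¹ (at unit neutral fraction),
σ_max = 0.003 C·m⁻², K_part = 30 µM place the dip-then-rise crossover of a
pKa-10.2 amine at tens of seconds and ~30 µM, matching the qualitative
observations; only shape properties are asserted about it.  Acidifying the
bath from pH 7.4 to 5.5 suppresses loading ~79-fold (Henderson–Hasselbalch).

## 5. Displacement currents

ΔΦt(t) factorises as ΔΦt_max·θ(t) (linear-response assumption; `exact`
mode re-solves the field per time point for cross-checking — at the
reference condition the charge response is ~15% superlinear in Δσ, at
physiological screening linear to <1%).  C_total defaults to the geometric
A·c_b.  Closed-form mode uses the full-amplitude relaxation
i = C·ΔΦt_max·k_app·e^(−k_app t); total charge C·ΔΦt_max is conserved to
0.1% and the peak is C·ΔΦt_max·k_app exactly.  I–V tables normalise to the
largest-magnitude amplitude with sign preserved; slopes are ordinary least
squares per mV.

## 6. Capacitance measurement emulation and estimation

The equivalent circuit (R_S series; R_M ∥ C_M, with a V_Φ battery in
series with C_M; stray capacitance charging with τ_stray = 10 µs) is
driven by ±40 mV, 200 Hz bipolar square waves, evaluated
piecewise-analytically per half-cycle (exact, including unsettled
relaxations), filtered by a causal 4th-order Bessel low-pass at 10 kHz
(order is a choice; unspecified in the source) and sampled at 100 kHz.
V_Φ is inert in this linear circuit — it only sets the DC charge on C_M —
which is precisely why apparent-capacitance changes must come from the
surface-potential physics, not the circuit.

Estimation proceeds per half-cycle: discard the first six samples after
each step (the stray transient completes within 60 µs), fit the
relaxation, and invert (step jump, steady-state change, τ) to
(R_S, R_M, C_M) using the *previous* half-cycle's fitted relaxation for
the pre-step current — exact even when relaxations do not settle.  Two
modes:

- `exponential`: bare three-parameter fit; machine-exact on unfiltered
  noise-free traces (the 1000-point recovery grid passes at ≤0.1%).
- `filtered_model` (default on filtered traces): the candidate circuit's
  ideal response, plus a free stray-amplitude term, is passed through the
  known Bessel filter before comparison.  A bare exponential fit on
  filtered data would carry a ~20% C_M bias (filter group delay ~34 µs
  against τ ~150 µs); the filtered-model fit removes it (<10⁻⁴ residual
  bias), standing in for the hardware-transfer-function deconvolution used
  with real amplifiers.

Per-fit failures are skipped with a warning; fits with residual RMS above
5× the median are excluded.  Per-cycle estimates are block-averaged to the
output rate (200 Hz → 50 Hz default, four cycles per point).  The
estimates are insensitive to a 1 MΩ R_S perturbation and to doubling the
stray capacitance (both ≪1 fF), and independent of V_Φ.

## 7. Synthetic data and what passing tests show

Generators emulate: capacitance traces (50 Hz, 5 s, white Gaussian noise
of SD 4.84 fF at the C_M level — the published trace-noise statistic;
optional linear drift), displacement-current traces (0.5 pA post-filter
noise, a stand-in since no current-noise figure is published),
concentration-response sets (13 cells, noise SD 5% of maximum),
I–V series (log-normal cell-scale factor, SD 0.3, motivated by the
reported spread of saturating responses), and raw square-wave records
(current noise fed through the full estimator, the end-to-end alternative
to C_M-level noise injection).  Every dataset serialises its generating
truth; every downstream fit is tested for recovery against it.  All
randomness flows through one seeded `numpy` generator per dataset;
identical seeds give bit-identical output.

What this does *not* show: the generators share the forward model with the
analysis, so green recovery tests validate the pipeline's internal
consistency and its statistical behaviour at realistic noise — not the
model's adequacy for real membranes.  Real recordings add amplifier noise
spectra, seal instability, endo-/exocytosis capacitance steps, voltage-
dependent protein transitions (e.g. the slow transient seen at +50 mV in
transporter-expressing cells) and transport-cycle currents, all outside
scope.

## 8. Numerical choices

- Coupled charge balance: alternating bracketed Brent refinement per face
  (each face's balance is strictly decreasing in its own potential, so the
  solution is unique) from a three-capacitor linear-circuit initial guess,
  then Newton polish in extended (longdouble) precision returning the best
  float64-representable point.  Residuals sit at the float64 floor:
  median <10⁻¹⁵, worst ~6×10⁻¹⁵ of max(|σₒ|,|σᵢ|,0.1·c_b) over random
  draws — the corner cases are limited by the 64-bit resolution of the
  potentials themselves, not by convergence.
- Sensitivity analysis: the ΔC_M-vs-Δσ response is linearised by central
  difference (half-width 10⁻⁵ C·m⁻²) around Δσ = 0; the inversion warns if
  the threshold charge leaves the linear regime (secant deviating >20%).
  Density = Δσ_min/(e·c_b·charges-per-site)·10⁻¹², in units per pF.
- Hyperbola fits: positivity-bounded Levenberg–Marquardt/TRF with a
  half-maximum interpolation seed; default normalisation divides by the
  fitted maximum and refits once.  Standard errors from the Gauss-Newton
  covariance throughout; no bootstrap by default.
- Monoexponential fits seed from a log-linear regression of the
  sign-consistent post-peak segment.
- Strict SI internally; mV/pA/fF only at I/O boundaries.  Electrolyte
  concentrations in mol·m⁻³ (numerically equal to mM); ligand
  concentrations in mol/L to match M⁻¹s⁻¹ rate constants.

## 9. Problem sizes used by the shipped analyses

The acceptance script fits 100 seeded 13-cell × 8-concentration
dose-response replicates (t2) and one deterministic sensitivity inversion
(t5); the test suite's largest jobs are the 10×10×10 circuit-recovery grid
and a 160-cycle noisy estimator calibration.  All sizes were chosen so the
statistical assertions are stable across seeds while the whole suite runs
in well under a minute on one core.

## 10. Known limitations

- The reference screening condition is a reconstruction of unreleased
  simulation inputs; at face-value physiological screening all
  ligand-induced capacitance signals are orders of magnitude smaller (§2).
  The fact that the measured ≈ −500 fF cocaine effect is nevertheless
  real suggests physics beyond the bare Gouy-Chapman layer (finite ion
  size, low local permittivity, protein-surface effects) that this model
  does not contain.
- The step-convention estimator cannot produce the sign asymmetry between
  leaflets; the level convention can, but exaggerates outer-leaflet
  magnitudes at dilute screening.  Neither convention reproduces every
  published panel simultaneously (§1).
- Inner-leaflet accumulation is a documented phenomenological stand-in.
- No Stern layer, no spatially resolved Poisson-Boltzmann solution, no
  competitive multi-ligand binding, no transport-cycle or gating currents,
  no vendor binary formats.
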