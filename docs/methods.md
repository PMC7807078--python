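# Methods

## Scope and data

The package correlates saturation mole-fraction solubility y(T, P) of a
solid solute in supercritical CO₂ with five classic three-parameter,
density-based models (Chrastil; Bartle; Méndez-Santiago–Teja, MST;
Kumar–Johnston, KJ; Garlapati–Madras), and derives the standard secondary
quantities: AARD% model ranking, dissolution enthalpies, cross-over
pressure, and the MST self-consistency test.

The bundled dataset is a 32-point gravimetric solubility table for
decitabine (M = 228.21 g/mol) on the grid {308, 318, 328, 338} K ×
{12, 16, …, 40} MPa, transcribed verbatim with its per-point standard
uncertainties. One printed uncertainty — u(y) = 5.81×10⁻⁵ at
(308 K, 32 MPa), ~29% relative where every other row is below ~9% — is
kept as printed and flagged in `SolubilityDataset.notes` rather than
silently corrected.

Canonical units everywhere: K, MPa, mole fraction, kg/m³. Temperatures are
used as tabulated (308 K, not 308.15 K); a 0.15 K offset changes densities
by well under 1% and is absorbed by refitting.

## CO₂ density

All five models take the density of *pure* CO₂ at (T, P); the dilute-
solution assumption neglects the solute's effect on fluid density.

* **`reference` (default).** A grid of densities at 1 K × 0.5 MPa
  resolution over 303–343 K, 0.1–45 MPa, tabulated from the Span & Wagner
  reference multiparameter Helmholtz equation of state (the formulation
  behind NIST-quality CO₂ tables) and interpolated bicubically. The
  generating script (`scripts/make_density_grid.py`) self-checks the EOS
  against the critical point (7.3773 MPa at 304.1282 K, with a flat
  isotherm), the well-known saturation pressures at 273.15 K (3.485 MPa)
  and 293.15 K (5.729 MPa) via a full Maxwell construction, the second
  virial coefficient B(300 K) ≈ −121 cm³/mol, and the ideal-gas limit.
  Interpolation error at off-node points in the working envelope
  (308–338 K, 12–40 MPa) is below 0.1%; requests outside the grid raise a
  range error rather than extrapolate.
* **`pr-eos`.** A self-contained Peng–Robinson EOS (Tc = 304.13 K,
  Pc = 7.377 MPa, ω = 0.2239; largest real compressibility root), with a
  small density-dependent volume correction — a Péneloux-style translation
  whose six coefficients were calibrated once against the reference grid
  over 307–341 K, 10–45 MPa. Plain PR under-predicts dense-CO₂ density by
  up to ~9% near the critical region; the corrected form stays within ~3%
  of the reference over the working envelope (the two-provider agreement
  is asserted at 5% in the tests). Outside that envelope, particularly
  below ~10 MPa near Tc, the correction is extrapolated and accuracy
  degrades; the reference provider should be used there.

Molar density (used by KJ) is mass density / 44.01 g/mol.

## Calibration objectives

"Fitting" these models traditionally means multiple linear regression on
the linearized response — e.g. regressing T·ln(yP/P_ref) on (1, T, ρ) for
MST. That is `objective="linear"`, the default: deterministic, unweighted
OLS, with an explicit collinearity error when the design is rank-deficient
(e.g. a single isotherm).

Published parameter tables in this literature, however, generally
correspond to a different optimum: least squares on the *relative
deviations* (y_calc − y_exp)/y_exp in mole-fraction space, which is
(nearly) the AARD% by which fits are judged. The two objectives differ
noticeably here because the linearized responses weight the low-pressure,
low-solubility points differently: on the bundled dataset, OLS gives
AARD = 9.5% (KJ) but 16.7–18.4% for the other four, whereas the published
parameter sets evaluate to 9.2–14.6% on reference densities — they sit
near the relative-deviation optimum, not the transformed-space one.
`objective="relative"` therefore refines the OLS solution by
Levenberg–Marquardt on the relative residuals; it reproduces the published
analysis (KJ 9.01%, MST 12.37%, ΔH_total 58.5 kJ/mol, ΔH_vap 78.8 kJ/mol)
and is what the reporting script uses. Our converged relative fits for
Chrastil/Bartle/Garlapati–Madras reach 12.6–12.9% AARD, slightly *better*
than the 13–15.3% in the published table (whose Bartle triple, for
instance, evaluates to 13.9% on reference densities — consistent with a
not-fully-converged solver there). The published Chrastil parameter row is
internally inconsistent (its printed order/signs cannot reproduce either
the data or the quoted enthalpy) and is treated as garbled; Chrastil
results rely on refitting only.

On noise-free model-generated data both objectives recover the generating
parameters exactly (the relative refinement starts at the OLS solution,
which is already a zero-residual point), which the tests assert at 1e-6
relative.

AARD% uses the standard definition (100/N)·Σ|y_calc − y_exp|/y_exp — with
the absolute value and the 1/N, without which the quantity would not be a
positive bounded score.

## Enthalpies

ΔH = −b·R with R = 8.314 J/(mol K) converts a fitted 1/T coefficient into
kJ/mol: the Chrastil slope gives the total dissolution enthalpy, the
Bartle slope the vaporization enthalpy, and Hess's law gives
ΔH_sol = ΔH_total − ΔH_vap (enforced exactly by construction in
`EnthalpyReport`). The sign convention makes the physically usual negative
b map to positive enthalpies. Note ΔH_sol is a small difference of two
large fitted numbers, so its relative uncertainty is intrinsically several
times larger than theirs.

## Cross-over pressure

The operational, grid-based definition: classify the y-vs-T trend at each
tabulated pressure (two values tie only below 1e-12 relative difference —
never on real data) and report the smallest pressure whose trend is not
strictly decreasing, i.e. the exit from the density-dominated regime. On
the bundled table this gives 16 MPa (12 MPa strictly decreasing, 16 MPa
non-monotonic, ≥20 MPa strictly increasing). The detector is invariant to
record order and to uniform rescaling of y, and refuses incomplete grids
(it lists the missing cells). A continuous, model-based variant
(`model_crossover_pressure`) solves y(T_min, P) = y(T_max, P) on a fitted
correlation by bisection; its default bracket starts at 10 MPa because
fitted isotherms can exhibit a spurious second crossing in the
near-critical region.

## MST self-consistency

With the fitted density coefficient c, Γ = T·ln(yP/P_ref) − c·ρ should be
a single straight line a + b·T across *all* isotherms if the correlation
extrapolates. The test pools every record into one OLS line and reports
R², the line, and each isotherm's mean absolute deviation from it. On the
bundled data R² ≈ 0.94 and the deviation grows with temperature (largest
at 338 K), the signature of the sublimation-pressure term outgrowing the
correlation's temperature dependence. A single-isotherm input is rejected
as degenerate (slope and intercept are not separately identifiable).

`extrapolation_test` fits on a retained subset and returns the AARD% of
the held-out predictions; for the bundled data, holding out the 40 MPa
row and predicting it with MST gives ≈31% — extrapolation is meaningful
but distinctly worse than interpolation.

## Synthetic surfaces

The generator emulates exactly what the estimators assume: a chosen
correlation evaluated on a T×P grid with multiplicative lognormal noise,
y = y_model·exp(ε), ε ~ N(0, σ²) i.i.d., u_y = σ·y. Relative noise mirrors
how the measured uncertainties scale with y; σ defaults to 0.05, the order
of the ~9% maximum relative scatter typical of gravimetric measurements.
Replicate studies spawn per-replicate streams from one root seed, so any
study is reproducible from a single integer. What the generator does *not*
emulate: systematic density errors, temperature-dependent noise,
equilibration failures, or any misspecification of the functional form —
so passing recovery tests demonstrates correctness of the machinery, not
that real solubility surfaces follow these models.

Default study sizes (32-point grids, 30–100 replicates) keep every
simulation in the test suite and the reporting script within seconds while
leaving Monte-Carlo error well below the asserted effects.

## Known limitations

* The density source used for any published parameter table is rarely
  stated; reproduction of fitted parameters is therefore tolerance-based.
* Unweighted objectives: per-point uncertainties u_y are carried through
  the data model but not used as regression weights.
* No uncertainty propagation into parameter covariances or enthalpy error
  bars; no sublimation-pressure modeling; no cosolvents or multi-solute
  systems; cubic-EOS/SAFT *solubility* models are out of scope (the cubic
  EOS here is only a density provider).
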