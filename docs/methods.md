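# Methods

This note records the models implemented in `filadose`, their assumptions,
the defaults that matter, and the design choices made where the underlying
procedures are genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Hansen screening

Cohesive energy density is partitioned into dispersion, polar and
hydrogen-bonding components δd, δp, δh (MPa^1/2); the total parameter is the
Euclidean norm of the triple and the miscibility distance between two
materials is

    Ra = sqrt(4 (δd1−δd2)² + (δp1−δp2)² + (δh1−δh2)²),

the standard Hansen metric with its factor 4 on the dispersion axis. `Ra` is
a true metric (a scaled Euclidean distance), which the suite property-tests.

Screening rule for passive loading: a combination is *favoured* when the
drug–solvent distance exceeds `t_high` (default 10 MPa^1/2 — the solvent must
hold the drug weakly so it partitions into the polymer) and the
solvent–filament distance lies within `width` (default 3) of `t_mid`
(default 10 — enough affinity to swell the filament, not enough to dissolve
it). Exactly one criterion gives *borderline*, neither gives *rejected*.
The scalar `rank_score = Ra_drug_solvent − |Ra_solvent_filament − t_mid|` is
a package-defined convenience for sorting only; it has no physical meaning
and the raw distances are always reported next to it. An interaction radius
`Ro` can be carried as an annotation, but no Hansen-sphere fit is performed.

Group-contribution estimation uses the Hoftyzer–van Krevelen forms
δd = Σ(nFd)/V, δp = sqrt(Σ(nFp²))/V, δh = sqrt(Σ(nEh)/V) with the additive
Fedors molar volume V. The bundled table deliberately omits groups with
non-positive Fedors volume increments (>CH−, >C<) so that additive volumes
stay positive; molecules containing them need `molar_volume_override` (from
a measured density and molar mass), which is the more accurate route anyway.
Group counts are user input — no structure parsing is attempted.

For the bundled nifedipine reference set, tabulated literature triples are
used rather than group estimates. Note one internal inconsistency of that
tabulation: the printed total parameter of ethyl acetate (18.1) differs by
0.054 from the norm of its printed components (18.154); the package always
reports recomputed values and never forces agreement with a printed total.
The same applies to the tabulated solvent–filament distances, which are not
reproducible from the printed triples; only recomputed distances are used.

## Diffusion kinetics and dose geometry

A filament section (nominally 1.0 cm × 1.75 mm, closed-cylinder area
S = 2πr² + 2πrh ≈ 0.598 cm²; the reference experiments quote 0.604 ± 0.024
cm², about 1 % above the nominal-geometry value) is immersed in saturated
drug solution and the cumulative extracted drug mass M(t) is recorded.
The steady-state flux is the OLS slope of M/S against time over the linear
loading window. Choices fixed here:

* replicates are averaged per time point before the regression (the flux is
  defined on the mean uptake curve);
* the window defaults to 0–4 h, the linear portion of the reference uptake
  curves, and is overridable per dataset;
* the intercept is free, not forced through the origin — the flux is a slope
  definition and a non-zero intercept (surface deposition, extraction bias)
  should not contaminate it;
* masses are normalised by the nominal section area, not per-section
  measured areas. Units are fixed at hours/mg/cm throughout the library;
  conversions happen only at the I/O boundary.

Permeability is P = Jss/Csat with Csat the saturation solubility in the
loading solvent, and the enhancement ratio is the plain flux ratio between
solvents for a filament. No Fickian PDE is solved — the treatment is purely
regression-based, so only the initial-linear-uptake regime is interpreted.

Tablet sizing is closed-form cylinder arithmetic: mass = dose/loading,
volume = mass/density, height from the cylinder volume; the round trip
volume·density·loading = dose is exact and property-tested.

## Dissolution kinetics

The four release laws are each fitted by least squares *on their stated
scale*: zero order on Q vs t through the origin; first order on ln Q vs t;
Hixson–Crowell on the cube-root transform through the origin;
Korsmeyer–Peppas on the fractional scale by bounded nonlinear least squares
(log–log start values). Fitting on the transformed scales matches the
linearised convention of the dissolution literature, and R² is computed on
the fitted scale so that model comparison follows the same convention.
The Korsmeyer–Peppas fit is restricted to points with fractional release
≤ 0.6 by default (the customary validity range of the power law; set the cap
to 1.0 to use the full profile — whether a full or truncated range was used
in the reference analysis is not stated, so both are supported).

Model selection is by maximum R², ties broken by fewer parameters and then a
fixed model order, and is invariant to the order models are requested in.
Mechanism classification from the power-law exponent uses the
geometry-specific Fickian thresholds 0.50 (thin film), 0.45 (cylinder) and
0.43 (sphere), *anomalous* between the threshold and 1, and zero-order
transport at n ≥ 1 (at n = 1 the power law is algebraically zero order,
which the suite asserts as an identity, K_KP = K0/Q∞).

Assay hygiene: cumulative release must be non-decreasing; negative
decrements up to 0.5 % of Q∞ are treated as assay noise and clipped to the
running maximum before fitting, larger ones are rejected as data errors.
A cumulative sample-withdrawal correction (adding back drug removed with
each aliquot, with support for a mid-run medium-volume change) is provided
as an optional preprocessing step and is off by default, since the reference
analysis does not state that it was applied.

## Accelerated stability and shelf life

Per chamber condition the percent-degraded curve d(t) is fitted to five
kinetic laws (zero, first, second order, square-root diffusion, Avrami with
exponent 2), each by least squares in its functional form with d∞ = 100 %
unless configured otherwise. Two conventions had to be pinned down:

* **Scale.** Assays report percent *remaining*; the kinetic forms describe a
  quantity rising from zero. Observations carry an explicit convention flag
  and are converted to percent degraded at ingest; all fitting and inversion
  happens on the degraded scale.
* **Avrami form.** The canonical fraction form
  d = d∞(1 − exp(−k t²)) is the default; the literal remaining-percent form
  `remaining = d∞ − exp(−k t²)` (which is dimensionally inconsistent at
  t = 0, where it pins 1 % degradation) is available behind the
  `as_printed` flag for comparison only.

Rate constants carry model-specific units (%/day, day⁻¹, day⁻², …),
reported as explicit unit strings. Flat (all-equal) data yields k = 0 with a
flat-fit marker rather than an error.

The condition-wise constants are regressed on the humidity-corrected
Arrhenius surface ln k = ln A − Ea/(R·T) + B·RH by OLS with regressors 1/T
and RH, R = 0.00198 kcal K⁻¹ mol⁻¹, requiring at least three conditions
spanning two temperatures and two humidities (rank-deficient designs are
rejected by name). Shelf life inverts the chosen kinetic law in closed form
at the extrapolated storage-condition rate (defaults 25 °C, 60 % RH, 10 %
limit); the forward curve evaluated at the returned day reproduces the limit
to 1e-9, which the suite asserts for every law.

One quantitative caveat surfaced by the synthetic design: with an activation
energy near 23 kcal/mol, a parameter set implying a ~3-year shelf life at
25 °C drives the 80 °C chambers past 100 % degradation within the first
14-day sampling point. The synthetic defaults (ln A ≈ 32.5) therefore keep
all six chambers inside the assayable range; they reproduce the *scales* of
the reference study (Ea ≈ 23 kcal/mol, B ≈ 0.008/%RH), not its raw data,
which were never published.

## Mechanics

Roughness: Rav is the mean absolute deviation of trace heights from their
mean; Rz is max − min over the *whole* sampling length (deliberately not the
ISO 4287 five-sub-length average, matching the instrument convention of the
reference measurements). Both are offset-invariant and homogeneous of
degree 1 in the heights, which the suite property-tests.

Bending modulus: the gradient of the initial linear section of the
three-point-bend force–travel record. How that section is delimited is not
standardised, so the package defines it: an OLS line is fitted to a minimum
prefix (at least 15 % of the travel range, ≥ 5 points; if even this prefix
has R² < 0.99 the record is flagged and the minimum-prefix slope returned
with a warning) and grown greedily while each next point stays within a
residual band around the running fit — the larger of 3× the fit's RMS
residual (tracks measurement noise) and 1 % of the predicted force (catches
a noise-free yield kink within about one sample). A global R² guard alone
was rejected: the R² of a monotone bilinear curve stays above 0.99 far past
the yield point, biasing the slope low, whereas the residual band stops at
the breakpoint within one sample on the same curve. Toughness is the total
trapezoidal area under the force–travel curve; no beam-theory conversion to
a true flexural modulus is attempted (the raw gradient, in the N·mm
convention of texture-analyser software, is what enters the feature table).

## Multivariate model

The feature table holds one row per (solvent, filament) combination and six
columns: solvent–filament Ra (recomputed, not tabulated), blank-filament
Rav, bending modulus, toughness, Jss and permeability. "Stiffness" as a
model input is mapped to the toughness (area under the bend curve); a config
switch substitutes the bending modulus. Blank-filament mechanics are used
for both solvents (loaded-filament mechanics change during soaking and are
not available per combination).

PCA runs on standardised columns; correlation loadings are the Pearson
correlations of each original variable with each score vector (the quantity
shown in correlation-loading plots) and the suite cross-checks the loadings
against a direct eigendecomposition of the correlation matrix.

Flux regression standardises features and target, then fits MLR, PLS
(2 latent variables by default, bounded by rows − 1) or an RBF-kernel SVM.
SVM hyperparameters come from an exhaustive grid
(C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 0.5, 1, 2},
ε ∈ {0.001, 0.01, 0.05}). The default selection criterion is the
**training-set** R²: the reported goodness of fit is a training fit (the
reference analyses were training fits, and eight rows cannot support a
held-out claim), so selection is aligned with the reported statistic; ties
keep the first (smallest-C) candidate, making the whole procedure
deterministic. Leave-one-out tuning is available (`svm_tune="loo"`), and the
leave-one-out R² of whatever hyperparameters were selected is always
reported alongside as an honesty diagnostic — on the eight-row reference
table it is strongly negative, which is the package's explicit statement
that the model memorises rather than generalises at this n. No
external-validation machinery beyond LOO is provided, deliberately.

## Synthetic data

Every generator is a pure function of its truth parameters and a
`GeneratorSpec` (seed, noise family, noise scale); identical inputs give
bit-identical output, and at zero noise each generator is the exact inverse
of its estimator (asserted pairwise in the suite). Noise families are
additive Gaussian (scale relative to a reference magnitude) and
multiplicative lognormal (scale = σ on the log axis).

* **Uptake curves** are linear at the true flux up to a plateau time
  (default 4 h), then approach the asymptote exponentially (time constant
  2 h), emulating the sharp-rise-then-saturation shape of measured loading
  curves; replicates receive independent noise.
* **Dissolution profiles** forward-evaluate a release law, clip to
  [0, Q∞], and enforce monotonicity after noise.
* **Stability studies** draw per-condition rate constants from the
  Arrhenius surface and evaluate the chosen degradation law at the sampling
  days (default design: six chambers at 50–80 °C / 10–75 % RH, sampled at
  days 14/28/48).
* **Roughness traces** are rescaled zero-mean Gaussian noise whose realised
  Rav equals the target exactly, by construction.
* **Force curves** are linear at the true modulus to the yield travel, then
  plateau with a gentle linear decline; noise is post-yield only so the
  elastic gradient stays exactly recoverable at zero noise.

What the generators do *not* emulate: correlated assay drift, photodegradation
of the loading solution, polymer swelling dynamics, instrument quantisation,
or heteroscedastic HPLC error. Passing recovery tests therefore demonstrate
estimator correctness under the declared noise families at the study's
scales — not robustness to every artefact of real instrument data.

Problem sizes used in the simulation-based tests — 500 seeded uptake fits at
5 % noise, 200 release-model selections at 2 % noise, 500 Arrhenius
replicates at 2 % noise on the rate constants — were chosen to make the
asserted rates (≥ 95 % flux recovery within 10 %, ≥ 90 % correct model
selection, < 2 % activation-energy bias) stable across re-runs while keeping
the default suite fast.

## Known limitations

* Screening thresholds encode one drug's loading behaviour; they are
  configurable but their defaults should not be read as universal.
* Dissolution and degradation fits assume a single mechanism over the fitted
  range; medium switches are carried as metadata, not modelled.
* The flux model is descriptive at n = 8; predictions outside the convex
  hull of the training descriptors are extrapolations of an interpolator.
* Group-contribution HSP estimates inherit the additivity assumption and the
  bundled table's provenance; tabulated values, when available, take
  precedence.
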