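# Methods

## The FAC model

Frontal affinity chromatography treats the lectin column as a bed of
identical, independent sites of total content Bt (nmol). Continuous
infusion of analyte at concentration [A]₀ gives a breakthrough front whose
elution volume exceeds that of a non-binding standard by

    V − V0 = Bt / (Kd + [A]0)

(the retardation form of the single-site isotherm). Inverting gives
Kd = Bt/(V − V₀) − [A]₀, and the simplified Kd = Bt/(V − V₀) whenever
[A]₀ ≪ Kd; the relative error of the simplification is exactly [A]₀/Kd,
below 1.3 % at the standard 2.5 nM infusion for any Kd ≥ 2 × 10⁻⁷ M.
Units are fixed at Bt in nmol, volumes in µL, concentrations in mol/L;
the identity nmol/µL ≡ mmol/L carries the 10³ conversion, pinned by the
dimensional check 1 nmol / 1000 µL = 10⁻⁶ M.

Assumptions: one class of independent sites, equilibrium at the flow rate
used, no cooperativity, no temperature or dispersion corrections. These
match how the underlying assay is routinely analyzed; multi-site models
are out of scope.

## Column calibration

Bt and the reference Kd come from a concentration-dependence series via
the Woolf–Hofstee plot, (V − V₀) vs (V − V₀)[A]₀, fitted by **unweighted
OLS on the transformed coordinates** — deliberately the estimator the
instrument workflow describes, not a nonlinear refit of the hyperbola.
Kd = −1/slope; Bt = intercept × Kd × 10³ (µL·mmol/L → nmol). A
non-negative slope is reported as "no saturable binding", an error, never
a clamped parameter. Fewer than 3 points, fewer than 2 distinct [A]₀
values, or a zero-variance design raise an insufficient-data error.

The series' [A]₀ ladder is not published; the default design is
{0.1, 0.3, 1, 3, 10} × Kd, five points spanning the saturation curve
symmetrically about Kd. On noiseless data the fit recovers the generating
(Bt, Kd) to better than 10⁻⁶ relative; at 2 % multiplicative retardation
noise the median relative Kd error over 500 replicates is ≈1.9 %
(invariant across the three reference columns, because the design scales
with Kd and the noise is multiplicative).

Reference calibrations carried as constants (`REFERENCE_CALIBRATIONS`):
PPL2A Bt = 0.02 nmol, Kd = 2.0 × 10⁻⁷ M; PPL3s 0.63 nmol, 3.01 × 10⁻⁵ M;
PPL4 0.98 nmol, 2.0 × 10⁻⁵ M — all on the 31.4 µL miniature column.

## Front detection

The instrument's internal front-finding algorithm is not documented, so
two surrogates are implemented. Baseline is the median of the leading
fraction of samples (default 5 %; the simulation pipeline uses 2 % because
its standard front sits at the 31.4 µL bed volume of a long grid), plateau
the median of the trailing 10 %; detection requires a plateau rise of at
least 5× a MAD-based noise estimate.

* **half_height** — interpolated crossing of (baseline + plateau)/2 on a
  lightly smoothed (5-sample moving average) copy; the smoothing does not
  shift the center of a symmetric front.
* **equal_area** (default) — the mass-conserving front position
  V* = a + ∫ₐᵇ(plateau − s) dv / (plateau − baseline), with the window
  [a, b] placed around the transition (quartile crossings padded by 5×
  the 25–75 % rise width, at least 10 grid steps). The windowing matters:
  integrating the deficit over the *whole* trace is algebraically
  identical but its noise variance grows with trace length, and on the
  1200 µL grids needed for slowly eluting glycans the full-trace
  integral's ≈0.35 µL error would routinely cross the 0.5 µL detection
  floor and create spurious "binders". With the window, the mean absolute
  front error at 2 % noise is ≈0.09 µL (< σ/10 for the σ = 1.5 µL fronts).

Both estimators are exactly translation-equivariant and scale-invariant,
and agree to < 0.01 µL on noiseless symmetric fronts.

## Below-detection convention

Retardations at or below v_min = 0.5 µL (configurable) are flagged
`below_detection`; their Ka is reported as 0 in profiles and they are
excluded from relative-affinity normalization. The instrument's true
detection floor is not published; 0.5 µL is a choice, stated here once and
used everywhere. A retardation that inverts to a non-positive Kd (noise
exceeding the model) is likewise flagged, with a warning.

## HAI logic

MIC: the concentration of the last well in the leading contiguous
inhibiting run of a 2-fold series. If the starting well does not inhibit,
the result is right-censored as "> start". Non-monotone patterns (an
inhibiting well below a gap) are resolved conservatively to the leading
block with a warning — plates are assumed monotone in dose, real plates
sometimes are not. Exact grid values are stored (7.8125 mM); display
rounds to two significant figures unless the exact value is already ≤ 3
significant figures (so 7.8125 → "7.8" but 6.25 and 12.5 print as
themselves), matching the mixed precision of assay tables. mM and %w/v
are tags, never interconverted. Titer: 2⁻ⁿ with n the last well of the
leading agglutination-positive run.

## Profiling and mJRL classification

Relative affinity is 100 × Ka / max Ka per lectin — max-normalization is
an assumption (the convention behind "relative affinity (%)" displays is
not formally defined anywhere we could pin down).

Classification thresholds (all explicit config, defaults in parentheses):

* **group A** iff the detectable fraction over the *mannose axis* — the
  high-mannose class plus core-pentasaccharide-flagged glycans — is
  ≥ θ_A (0.2); else group B. Core-pentasaccharide glycans count toward
  the axis because complex-type-preferring JRLs that bind only the trimmed
  Man₃GlcNAc₂ core among the mannose glycans still belong to group A.
* **subgroup 1** iff the detectable fraction over the complex-type classes
  (agalacto, galactosylated, sialylated) is ≥ θ_C (0.5) **and** the mean
  relative affinity of bisecting-GlcNAc-flagged complex glycans is ≤ ρ
  (0.5) × the mean of the non-bisecting complex glycans (the bisecting
  penalty is assessed by flag, not by explicit structural pairing);
* **unclassified** iff the complex-type fraction is < θ_min (0.1), with
  the failing criterion recorded in the evidence map;
* **subgroup 2** otherwise. The same subgroup logic applies within group
  B for symmetry, although the bundled archetypes only exercise group A.

All criteria are fractions and ratios, so classification is invariant
under uniform Ka rescaling.

Profile comparison reports the Pearson correlation of log₁₀(Ka + floor)
over the glycans detectable in **both** profiles, with floor = each
profile's detection-limit Ka (v_min·10³/Bt). Restricting to the
both-detectable set is deliberate: including floored below-detection
entries would let the floor, not the data, drive the statistic, and a
uniform ~100-fold affinity offset between paralogs would no longer score
as perfectly concordant. Discordant glycans are those detectable in
exactly one profile, or whose log-ratio deviates from the global median
offset by more than 1 decade.

## The synthetic world

The generator emulates, with stated parameters:

* **Panel** — 130 glycans: 61 N-linked (9 high-mannose including the two
  core-pentasaccharide sentinels 003/015, 6 hybrid, 18 agalacto,
  16 galactosylated, 12 sialylated), 39 glycolipid-type (including the
  mannose-arm sentinels 913 = α1-3 only, 914/915 = α1-6 only) and 30
  others (plant-core sentinel 017, chitin oligomers 101–104). The 61/39
  split is as stated for the real panel; the per-class split within the
  61 is a fixture choice. The panel is a *stand-in*, not a reconstruction
  of the unavailable appendix.
* **Archetypes** — `PPL2A_like`: complex-type classes + core
  pentasaccharide, skipping bisecting/tetraantennary glycans and 017,
  Kd center 2 × 10⁻⁷ M; `PPL3_like`: same support plus 017, center
  2 × 10⁻⁵ M (the ~100-fold weaker paralog); `PPL4_like`: high-mannose +
  hybrid + α1-6-arm + chitin-type, center 2 × 10⁻⁵ M, no complex-type
  binding; `nonbinder`. Per-glycan log₁₀ Kd deviations ~ N(0, 0.3),
  clipped at ±3 sd (keeps the slowest simulated fronts inside the default
  1200 µL grid), drawn from an RNG keyed by (seed, glycan id) and
  **shared across archetypes** so paralogs with common support differ by
  their centers exactly — independent draws would fabricate discordant
  glycans the stated world does not contain. The 0.3 sd is an invented
  dispersion.
* **Curves** — plateau × Φ((v − v_front)/σ) with σ = 1.5 µL (a dispersion
  surrogate, not physics) plus additive Gaussian noise of 2 % of plateau;
  grid default 0–1200 µL in 0.25 µL steps; standard front at the 31.4 µL
  bed volume; [A]₀ = 2.5 nM.
* **Plates** — deterministic: well k inhibits iff start/2ᵏ ≥ true MIC;
  optional well-flip noise for robustness tests only.

What a green end-to-end test establishes: the pipeline recovers the
parameters and classifications of *this* stated world (correct archetype
grouping in ≥ 95 % of 200 seeded runs; in practice 100 %). What it does
not establish: anything about real chromatographic dispersion, plate
misbehavior beyond monotone dose response, or the actual per-glycan
affinities of the real lectins, which are not publicly deposited.

## Numerical choices and degenerate inputs

* OLS via `numpy.polyfit` degree 1; r² from the residual sum of squares.
* Equal-area integral by the trapezoid rule on the raw (unsmoothed)
  signal; window edges snapped to grid points so an ideal step with a
  midpoint sample is recovered exactly.
* Curves require ≥ 20 samples and strictly increasing volumes; a grid
  step coarser than the front σ warns (aliasing).
* Seeds: every stochastic generator takes an explicit seed; streams are
  separated by per-operation salts and per-glycan CRC32 salts, so fixtures
  are independent yet bit-reproducible. All internal seeds stay < 2³¹.
* Censored and uncensored MICs never compare equal; report ordering keeps
  the censoring flag.

## Known limitations

* The classification thresholds reproduce the three archetype assignments
  by construction of their defaults; they are explicit config precisely
  because the grouping scheme publishes no numeric boundaries.
* `woolf_hofstee_fit` inherits the heteroscedasticity of linearized
  regression; the noiseless closures are exact, but at high noise a
  weighted or nonlinear refit would be more efficient. The linear form is
  kept as the primary estimator for fidelity to the assay's own analysis.
* The equal-area window falls back to a full-trace integral when the
  quartile crossings cannot be localized (degenerate rises).
* HAI units (mM vs %w/v) are never converted; cross-unit comparisons are
  meaningless without molar masses and are not attempted.
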