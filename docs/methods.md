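# Methods

This note documents the models, numerical choices and limitations behind
`icpd`. It describes what the code computes; every empirical number quoted
here is produced by the test suite or by `scripts/acceptance.py`.

## The measurement model

The unit of observation is an *analysis*: one chromatographic run of one
fraction — FAA (free amino acids, already released by natural peptide-bond
hydrolysis) or THAA (total hydrolysable amino acids, the whole pool
recovered after laboratory acid hydrolysis) — of one dated subsample. Each
analysis reports, per amino acid, a D/L enantiomer ratio (dimensionless)
and a concentration (treated as consistent-but-arbitrary units; the
absolute unit never enters any computation, only ratios and population
statistics). Asx and Glx are composite codes: the amide forms deaminate
during preparative hydrolysis, so acid + amide are reported together.

The internal time axis is **age in years before collection**, so D/L is
non-decreasing in age; calendar years exist only at the I/O boundary.
Fractional assigned years (sub-annual sampling) are carried through and
rounded only at reporting. Missing amino acids in a row are *absent*, not
zero: zero concentration is a physical claim, absence an analytical one.
D/L values above 1.1 are rejected at read time (racemization equilibrates
near 1).

## Quality screening

Closed-system diagenesis imposes covariance between variables measured on
the same subsample; compromised material breaks it. Screens run in a fixed
order, with earlier exclusions removed before later fits:

1. **Pre-cull** of gross deviants in the Asx–Glx THAA concentration plane:
   points whose orthogonal distance from the Theil–Sen line exceeds
   10 × the MAD of all distances. This replaces visual removal with a
   deterministic robust rule; the threshold is config-exposed. We use the
   median-slope line with the robust intercept `median(y − slope·x)` —
   the quantile-based intercept some libraries return is shifted a full
   rank by a single gross outlier, which defeats the purpose.
2. **Covariance test (i)**: FAA Asx D/L vs THAA Asx D/L, power family
   `y = a·x^b`. Because orthogonal regression is awkward for non-linear
   curves, the test is run twice with the dependent variable swapped;
   only points whose |standardised residual| exceeds the cutoff
   (default 2.5 sd) in **both** orientations are flagged. A flagged pair
   removes both the THAA and the FAA analysis of that replicate: the test
   cannot attribute blame to one fraction, and a broken pair means the
   subsample's protein is disturbed.
3. **Covariance test (ii)**: THAA Asx vs Glx concentration, linear,
   single orthogonal-distance fit (error in both variables); flags at the
   same cutoff on standardised perpendicular residuals. Exclusion is
   THAA-only — a concentration artefact does not impugn the FAA D/L.
4. **Covariance test (iii)**: THAA Asx vs Glx D/L, power family,
   dual-axis as in (i). A flag here also removes the same-replicate FAA
   analysis (disturbed protein, both fractions untrustworthy).
5. **Analytical duplicates**: per amino acid and fraction, the population
   of signed D/L differences between duplicate runs is collected over the
   whole dataset; a pair whose |difference| exceeds 4 × the population sd
   (ddof = 1, candidate included) is flagged. One tripped amino acid
   removes that amino acid's values from both duplicates; more than one
   removes both analyses entirely. The sd is of the *signed* differences:
   4 × the sd of absolute differences would sit at ≈ 3.4 analytical sigma
   and flag ~1.6% of perfectly clean pairs, which is not what a 4-sigma
   screen means.
6. **Concentration extremes**: THAA analyses whose total concentration
   (summed over amino acids; per-amino-acid mode is config-switchable)
   lies more than 2 sd from the full-dataset mean. The reference mean/sd
   for this screen and the duplicate-difference population are computed on
   the **full** dataset, not on survivors of earlier screens — they are
   population statistics of the measurement campaign.

Function selection fits each candidate family, rejects any whose fitted
curve has a negative gradient anywhere on the observed range (racemization
must progress), and picks the survivor with the best adjusted R²; AIC and
an F statistic are recorded but not decisive. Goodness-of-fit criteria are
computed from vertical residuals regardless of fitting mode, as they are
conventionally quoted on the response scale. Standardised residuals use
the sample sd (ddof = 1) of that fit's residuals; a residual sd at machine
precision relative to the data magnitude is treated as a perfect fit
(degenerate), not a population.

Because the cutoff applies to residuals standardised by a dispersion
estimated *with the outliers still present*, gross outliers inflate the sd
and protect clean points; on the default synthetic conditions the pipeline
recovers ≈ 92% of planted outliers with ≈ 1% false positives (see
`test_acceptance.py`). Exclusion counts are non-increasing in the cutoff;
exact set inclusion between cutoffs can fail on rare single analyses
because sequential staging changes which points reach later screens.

## Inter-study corrections

Both racemization and hydrolysis-induced racemization are thermally
activated, `k ∝ exp(−Ea/RT)`, R = 8.314 J mol⁻¹ K⁻¹, °C + 273.15.

* `arrhenius_rate_ratio(ea, t_a, t_b)` = exp((Ea/R)(1/t_b − 1/t_a)).
* `hydrolysis_offset` scales a protocol's induced D/L at D/L = 0 by the
  ratio of k(T)·t between protocols. The shipped legacy harmonisation
  applies a stored additive offset of 0.043 D/L plus a 13-year time-axis
  shift (`harmonise_legacy`); the Arrhenius machinery documents the
  offset's plausibility (Ea = 83 kJ/mol between 7 M HCl @ 110 °C/24 h and
  6 M HCl @ 150 °C/15 min) but does not re-derive it, since the underlying
  kinetic data are not available. No molarity correction is applied.
* `min_analysis_gap` computes the smallest whole-year gap between two
  studies' analysis dates from a collection date, an analysis lag and the
  other study's deadline.
* `compare_methods` fits an orthogonal line to paired measurements from
  two analytical methods and rejects 1:1 agreement when the joint 95%
  confidence ellipse for (slope, intercept), built from the ODR parameter
  covariance and an F quantile, excludes (1, 0). "No correction" is the
  default posture; the test exists to re-evaluate it on user data.
* `effective_temperature` models T(t) = Tmean + (range/2)·sin(2πt/yr),
  averages the Arrhenius rate over one period by trapezoidal quadrature
  (3650 nodes; the integrand is smooth and the cost negligible) and
  returns Teff = Ea/(−R·ln k̄) — the root of k(Teff) = k̄ in closed form,
  since the pre-exponential cancels. Jensen's inequality guarantees
  Teff ≥ Tmean with equality only at zero range. Activation energies are
  passed as magnitudes; the minus sign lives in the exponent. The
  small-amplitude check used in the tests is the Bessel approximation
  with the exact sinusoid harmonic mean,
  1/Teff ≈ 1/√(T0² − A²) − (R/Ea)·ln I₀(Ea·A/(R·T0²)), which agrees with
  quadrature to < 0.002 °C for ranges ≤ 8 °C; the cruder form
  ΔT ≈ ln I₀(x)·R·T0²/Ea overstates the uplift by O(A²/2T0) (~0.015 °C at
  a 6 °C range).

## The monotone Monte Carlo age model

For one series (core × amino acid × fraction), knots sit at the distinct
observed ages and the model value at a data age is the knot value —
duplicates enter as separate, equally weighted points. The fit minimises

    χ²(θ) + λ Σⱼ (log(max(sⱼ₊₁, ε)/max(sⱼ, ε)))²,

over knot values constrained non-decreasing, with ε = 1e−8 D/L/yr
flooring the slopes inside the logarithm (the constraint itself is
sⱼ ≥ 0: "always increases" is read as non-decreasing). λ defaults to 1.0
and is config-exposed; the penalty's *existence* is part of the method,
its weight is not prescribed, and at the default the penalty is a small
fraction of χ² on realistic series, so it smooths without biasing. The
optimiser is L-BFGS-B on (d₀, δ₁…δₘ₋₁) with δⱼ ≥ 0 bounds and an
analytic gradient, initialised from weighted pool-adjacent-violators; at
λ = 0 the solution equals weighted isotonic regression (verified against
an independent implementation in the tests).

**Uncertainty.** The per-series measurement sigma is the pooled (df-
weighted) standard deviation over all subsamples with replicate analyses,
assigned to every point of the series; series without replicated ages must
supply sigma explicitly. Each Monte Carlo iteration (default 5000; the
test profile uses 500):

1. perturbs every D/L by an independent normal draw with sd σᵢ
   (iterations producing a negative value are redrawn, capped),
2. refits the constrained model, warm-started from the base fit,
3. multiplies each segment slope by an independent lognormal jitter
   (log-sd `rate_jitter`, default 0.1) so that interpolation uncertainty
   between widely spaced samples is represented — the jitter distribution
   is a design choice, as only the existence of rate variation is
   prescribed — and
4. re-anchors the jittered curve to the perturbed data by the weighted
   least-squares vertical offset (jitter is applied after the solve; the
   alternative orderings are not distinguishable from the method's
   description, and post-solve jitter keeps the constraint exactly).

Envelopes are pointwise quantiles (50, 68.27, 95.45% — 1σ and 2σ bands)
of the ensemble on a uniform 1-year age grid spanning the observed ages.
Pointwise quantiles of monotone curves are monotone, so the median curve
inherits the constraint. Fixed seed + fixed config is bit-reproducible.

**Dating.** The ensemble estimator draws a D/L from
Normal(measured, σ_measured) per ensemble curve, inverts that curve (flat
segments invert to their midpoint; draws beyond a member's range clamp to
its endpoint age) and reports the median and central 68.3/95.4% intervals
of the inverted ages; measurements outside the whole ensemble's D/L span
are refused rather than extrapolated. The window estimator collects all
independently dated analyses within ± a D/L half-width (default 0.01) and
reports mean ± 1 sd / ± 2 sd; it requires ≥ 5 supporting analyses.
`envelope_overlap` resamples two envelopes onto a common grid and reports,
per grid age, whether the chosen-level bands intersect — disjoint bands
are statistically separated trajectories. `combine_cores` pools series
(ages are already relative to each core's collection) and re-estimates
sigma from the pooled replicate structure.

## The synthetic-data generator

The generator emulates the structure of a multi-colony coral AAR campaign
so that every stage can be validated against known truth. Defaults: 8
colonies, 16 subsample ages spanning 10–460 yr (giving 512 analyses with
duplicate FAA + THAA runs), power-law kinetics D/L = d₀ + a·ageᵇ with
b = 0.45 in both fractions and FAA amplitudes/offsets twice the THAA ones
(THAA Asx spans ≈ 0.05–0.35 over 500 yr, FAA Asx ≈ 0.1–0.7 — spans chosen
as realistic conveniences, not claims of fidelity); a reverse first-order
alternative tanh(k·age + artanh(d₀)) is available. Per-colony lognormal
rate multipliers (log-sd 0.1) are **shared across amino acids and
fractions** within a colony; with shared exponents the multiplier then
cancels exactly in every between-variable covariance plane. That is
deliberate: it reproduces the empirical situation in which screening
retains natural inter-colony variability (visible only in D/L-vs-age)
while covariance breaks indicate genuinely compromised material.
Analytical noise is normal per analysis (sd 0.005 THAA, 0.010 FAA D/L).
Concentrations decline linearly with age (to ~50% at 500 yr) with a
common per-run lognormal factor (5%: sample-mass/injection error moves
all amino acids of a run together, along the covariance ray) plus 2%
independent per-amino-acid noise; %FAA grows as
floor + (100 − floor)(1 − e^(−k_h·age)), k_h = 0.001/yr, floor 2%.

**Planted outliers.** One Bernoulli corruption event per physical
subsample, probability scaled so the expected labelled-analysis fraction
equals `outlier_fraction` (default 5%); styles and weights:
`dl_shift` (0.4) — a contaminant displaces every amino acid's D/L in both
fractions and both duplicates, independently signed per amino acid ×
fraction, magnitude 12 × the fraction's noise sd × U(0.75, 1.25), all
four analyses labelled; `conc_spike` (0.4) — the THAA pair's
concentrations ×5 or ÷5, either whole-sample (caught by the extremes
screen) or single-amino-acid (caught by the pre-cull / concentration
covariance); `dup_discord` (0.2) — one amino acid displaced in one
duplicate only, both members labelled since the pair is unusable.
Each style feeds one screening pathway, as the screens' validation
requires corruption that actually breaks the structure they test.

## What passing tests do and do not show

The generator's trajectories are exact power laws with exactly shared
exponents and colony multipliers; real data have curvature differences
between amino acids and fractions, temperature-history differences
between sites, and contamination modes (e.g. proportional shifts aligned
with the covariance locus) that are *invisible in principle* to
covariance screening. Screening sensitivity/false-positive numbers
therefore characterise the pipeline under corruption that breaks the
tested structure, not all real-world failure modes. Envelope and
inversion coverage are measured against the generator's own noise model
(normal, homoscedastic within a series); heavy-tailed analytical error
would degrade both. Dating precision numbers are generator-scale and not
comparable to any particular published dataset.

## Problem sizes and tolerances

The test suite uses 500-iteration Monte Carlo profiles (200 replicate
series for the calibration experiment, ~500 held-out inversions), 20
generator datasets for screening recovery, and 100 paired runs for the
pooled-vs-single comparison; `scripts/acceptance.py` reproduces the same
quantities at reduced replicate counts (10 / 60 / 40) as its desk-scale
profile. Optimiser tolerances: L-BFGS-B ftol 1e−12 / gtol 1e−10, 500
iterations max; quadrature 3650 nodes; envelope grid 1 yr. The
pooled-vs-single run statistic averages the window ci95 width over five
target D/L levels (ages 80–240 yr) because a single 8-point window sd is
too noisy to make the paired comparison stable.

## Known limitations

* No kinetic (Arrhenius-extrapolated) absolute dating: calibration is
  always against independently dated material from the same system.
* The ensemble inversion assumes the unknown sample shares the
  calibration colony's (or pool's) rate trajectory; between-colony rate
  spread must be represented by combining cores, which widens intervals.
* Covariance screening cannot detect corruption aligned with the
  covariance locus, nor anything in amino acids that no test covers
  (e.g. FAA Glx in the default test set).
* `scipy.odr` (deprecated upstream) is the ODR engine; its convergence
  codes with benign rank warnings on exact fits are accepted.
* No chromatogram processing: D/L and concentrations are taken as given.
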