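# Methods

## Calibration model

Each analyte is quantified from the analyte/IS peak-area ratio
y = A_analyte / A_IS. The calibration model is

    y = a0 + a1·x + a2·x²        (a2 ≡ 0 for linear analytes)

fitted by weighted least squares with weights w(x) = 1/x or 1/x² on the
*nominal* concentration x (not on the fitted response), the standard
bioanalytical convention. Weighting reflects the error model: detector
noise is approximately proportional to signal, so unweighted fitting
would let the top standards dominate and wreck accuracy at the LLOQ.
The fit is computed by QR-based least squares on the √w-scaled design;
tests verify agreement with the closed-form weighted normal equations to
1e-10 relative.

Duplicate calibration lines within a run (a full line at the beginning
and end of each run) are **pooled into a single fit** rather than fitted
separately and averaged: pooling uses all information, is
injection-order independent, and the two conventions coincide exactly
for balanced designs. Blanks and double blanks never enter a fit —
zero-concentration points are incompatible with 1/x-family weights.

The correlation coefficient *r* reported for a weighted (and possibly
quadratic) fit is defined as the signed square root of the weighted
coefficient of determination: R²_w = 1 − SS_res,w / SS_tot,w with both
sums weighted and the total sum taken about the weighted mean response;
the sign is the slope's. This is one of several defensible definitions,
so numerical equality with *r* values produced by vendor software is not
claimed.

A fitted curve must be strictly increasing on [LLOQ, ULOQ] (the
derivative a1 + 2·a2·x is checked at both endpoints; it is linear in x,
so the endpoints suffice). Non-monotone fits are rejected outright: a
curve that turns over inside its range cannot be inverted unambiguously.

**Back-calculation** inverts the curve at the observed ratio. Quadratic
inversion takes the root on the increasing branch inside [0, 1.2·ULOQ];
responses beyond that window are an error, not an extrapolation, because
above-ULOQ samples are handled by 20-fold dilution and re-assay (the
dilution factor multiplies the inverted concentration). A curve is
accepted when at least 75% of its back-calculated standards, and at
least six, fall within ±15% of nominal (±20% at the LLOQ, both
inclusive).

## Validation batteries and thresholds

All thresholds live in one `Thresholds` object (defaults: 20/5% blank
interference, 20/5% carryover, LLOQ/blank ratio ≥ 5, 15% QC and 20%
LLOQ accuracy and CV, 15% matrix-effect CV, 15% stability and dilution
windows). Boundary handling follows the wording of each rule: "less
than" criteria (selectivity, carryover) are **strict**, "within 15%",
"≤ 15%" and "at least 5×" are **inclusive**. Percentages are displayed
rounded to one decimal, but every verdict is computed at full precision,
so a verdict can never flip through display rounding. Every stored pass
flag is a pure function of the stored numbers and thresholds;
`recompute_pass` re-derives it, and tests assert the two agree.

CVs use the sample standard deviation (n−1). Between-run statistics pool
all 18 replicates (3 runs × 6) rather than averaging three run means —
matching an n = 18 between-run design. Each run's QCs are
back-calculated against that run's own calibration.

Matrix effect follows the three-preparation scheme: per donor lot,
ME = post-extraction-spiked / neat-solution response (×100), separately
for analyte and IS; IS-normalised ME = analyte ME / IS ME (×100);
recovery = pre-/post-extraction-spiked (×100). Acceptance rides on the
across-lot CV of the IS-normalised ME, which is what co-eluting matrix
actually threatens once an isotope-labelled IS is used.

Acid↔lactone interconversion is tracked as the proportion of the
*product* species within the acid+lactone pair, on a mass-concentration
(ng/mL) basis — the assay reports mass concentrations and the acid and
lactone masses differ by only one water, so a molar basis would shift
proportions by well under the bounds involved. Context bounds: 0.3
percentage points for acid→lactone, 5 for lactone→acid at room
temperature, 1.5 for lactone→acid on ice (all inclusive).

## Cohort analysis

Concentrations strictly below the analyte's LLOQ are censored and
excluded from every summary statistic (no imputation); a record exactly
at the LLOQ is kept. A per-analyte LLOQ override supports relaxing the
lactone limit to the parent compound's for cross-analyte consistency.
Records with a missing concentration are treated as censored.

Per-dose summaries report eligible n, above-LLOQ n and %, and median
(IQR) of the uncensored values using linear-interpolation quantiles (the
common default across major statistics environments; no convention was
mandated, and the reproduced targets — counts and proportions — are
insensitive to it). Reported percentages round half away from zero.

Visit-to-visit tracking is Pearson correlation of paired log₁₀
concentrations, dropping pairs with either visit censored. The storage
analysis is OLS of log₁₀ concentration on storage days (plus dose in mg
as a numeric covariate when adjusting). The "storage-specific R²" is the
**squared semi-partial correlation**: the increase in model R² when
storage is added to the dose-only model (equal to the plain model R²
when unadjusted). Partial R² would be another defensible reading; the
semi-partial is reported because it answers "how much observed variance
does storage account for".

## Synthetic generator

One injection is synthesised as

    A_analyte = (a0 + a1·C + a2·C²)·A_IS,nom·ME_lot·rec·(1+ε) + bg·(1+ε')
    A_IS      = A_IS,nom·ME_lot^κ·rec·(1+ε_IS)

with ε ~ N(0, CV²) proportional noise (CV 5% default, the level a
well-behaved MRM assay holds at mid-range), IS noise CV 2%, matrix
background bg = 150 counts against LLOQ responses near 2000 counts,
recovery rec = 0.95 applied to analyte and IS alike for extracted
samples (the IS is added before protein precipitation, so recovery
cancels in the ratio — as on a real instrument), and six matrix-lot ME
factors (1.0, 0.95, 1.05, 0.9, 0.8, 1.15) whose two extremes stand in
for a lipaemic and a haemolysed donor. The IS shares the lot factor
through coupling exponent κ (default 1), which is why IS-normalised ME
sits near 100% with small CV. Carryover contributes a fixed fraction
(2×10⁻⁴) of the top standard's response to the single blank injected
immediately after it. Interconversion moves a percentage of one
species' concentration to its paired partner *before* areas are
synthesised — the transfer is chemistry, not detection.

Slopes default to 1/(IS working concentration) — 0.04 for the 25 ng/mL
IS group, 1/55 for the lactones, 1/750 for CLP-CA — putting response
ratios near C/C_IS; CLP-CA adds a2 = −4×10⁻⁸ (≈ 11% droop at the ULOQ),
mild saturation that a quadratic absorbs without threatening
monotonicity.

The cohort generator draws per-dose true log₁₀ concentrations from a
bivariate normal across visits (correlation ρ), with dose-group means at
the observed per-dose medians of this drug class (single-digit ng/mL for
the statin analytes and bisoprolol, ~740 ng/mL for CLP-CA) and SD 0.4
log₁₀ units. Non-adherent patients (5% default) come from a near-zero
component (mean 10⁻¹·³ ≈ 0.05 ng/mL) that falls below the LLOQ with high
probability. Storage duration is N(2317, 470²) days clipped at 1 — a
multi-year biobank storage profile whose spread makes a slope of order
10⁻⁴ log₁₀/day detectable at n ≈ 600 with a storage R² near 4% — and the
drift B·storage acts on the M1 log₁₀ concentration. All outputs are
bit-reproducible from (config, seed); every random draw consumes the
stream even at CV 0, so record layouts match across noise settings.

What the generator does **not** emulate: retention-time-resolved
chromatograms (it starts at integrated areas), inter-day drift within a
run, correlated errors between analytes sharing an injection,
non-Gaussian heavy-tailed outliers, and real non-adherence patterns
(dichotomous mixture instead of graded partial adherence). Passing tests
therefore demonstrate correctness of the computational layer under its
stated error model, not robustness to every real-instrument pathology.

## Numerical notes and degenerate inputs

- Linear fits need ≥ 3 distinct levels, quadratic ≥ 4; fewer is a
  degenerate-design error, not a silent fit.
- A zero IS area makes the ratio undefined (error); a zero mean blank
  makes the LLOQ ratio +∞, which passes (and serialises as a JSON
  constant).
- Empty cohort strata yield n = 0 summaries with absent quantiles.
- ρ = ±1 cohorts are generated through the explicit bivariate
  construction z₂ = ρz₁ + √(1−ρ²)z₁', which stays valid where a
  Cholesky factorisation would fail.
- The storage-slope estimate in censored cohorts carries a small
  (≈ 0.25 SE) attenuation from informative censoring — low-storage
  samples of low-concentration patients are slightly more likely to fall
  below the LLOQ when B > 0. This is inherent to excluding censored
  values and is visible in the 2-SE coverage sitting just under the
  nominal 95%.

## Problem sizes

The shipped tests and the acceptance script use: 3 runs × 6 replicates ×
4 levels for accuracy/precision; 6 lots × 3 replicates for matrix
effect; 10 000 replicates for the CV-recovery check; 5 000 patients for
correlation recovery; 200 replicates of n = 600 for storage-slope
coverage; 1 000 random designs for the fitter oracle. These sizes give
each stochastic check comfortable power while keeping the whole suite
interactive.
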