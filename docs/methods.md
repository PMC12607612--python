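# Methods

## Scope and model

The package turns GC-MS peak areas into a dietary-risk characterization for
the four EFSA marker PAHs (BaA, CHR, BbF, BaP) in herbs and spices. The
chain is deliberately the standard surveillance one — internal-standard
calibration, left-censored summary statistics, TEF-weighted toxic
equivalents, point-estimate exposure, and margin of exposure — with every
step exposed as a tested function rather than a spreadsheet.

### Calibration and detection limits

Quantification uses the analyte-to-internal-standard peak-area ratio, fitted
against standard concentration by unweighted ordinary least squares (no
weighting scheme is assumed; five levels at 1, 2, 5, 10, 20 µg/kg is the
default design). Back-calculation inverts the fitted line; negative
back-calculated concentrations are preserved at this stage, since censoring
is a survey-level decision.

Detection limits follow the signal-to-noise convention: LOD = 3.3 σ/slope,
LOQ = 10 σ/slope, with σ the blank-baseline noise of the area ratio. The
noise estimator itself is an input (supplied in area-ratio units from blank
replicates) rather than something the package infers, because conventions
for estimating baseline noise vary by instrument software. A consequence of
the two constants is LOQ/LOD = 10/3.3 always; the tests assert it.

Accuracy is computed as 100 × mean measured / spiked. Recovery is
100 × (spiked − unspiked) / spike level. RSD is 100 × SD/mean with the n−1
denominator; intra-day precision pools replicates within one day, inter-day
precision is computed over day means.

### Censoring and summaries

Concentrations below the LOQ are substituted with zero and flagged censored.
Substitution by zero is the most conservative-downward convention; no
maximum-likelihood or Kaplan–Meier censoring estimator is provided, so
means and medians are biased low when censoring is heavy — which is exactly
the behaviour of the surveillance reports this package mirrors. A sample
counts as *detected* iff its concentration is at or above the LOQ; the LOD
plays no role in detection rates.

Quartiles use linear interpolation between order statistics (the convention
in which the sample maximum sits at cumulative position 1). SD uses the n−1
denominator. Report rounding is half-away-from-zero at 2 decimals.

Two PAH4 aggregates coexist on purpose. The per-commodity summary column
reported alongside the compound means is arithmetically the **mean** of the
four compound means, and `four_pah_mean` reproduces it; the EU maximum level
of 50 µg/kg regulates the **sum**, and `four_pah_sum` serves the compliance
check. Compliance comparisons are inclusive: a value exactly at the limit
passes.

### Risk chain

TEQ = Σ Cᵢ·TEFᵢ with default TEFs 0.1 (BaA), 0.01 (CHR), 0.1 (BbF), 1
(BaP). Two indices run through the chain: TEQ over BaP alone (against
BMDL₁₀ = 0.07 mg/kg bw/day) and TEQ over the PAH4 set (against 0.34). EDI =
TEQ × intake / body weight; µg/kg of food is numerically ng/g of food, so
the only unit conversion in the chain is the single mg→ng factor of 10⁶
applied to BMDL₁₀, and it lives in one place. Defaults: body weight
66.83 kg, MOE threshold 10⁴.

MOE at zero exposure is a typed "unbounded" sentinel, printed `>1e12`,
rather than a float infinity — report arithmetic on infinities silently
produces NaNs, and the sentinel makes that a type error instead. The
concern classification is inclusive at the boundary (MOE ≥ threshold →
low); the threshold is conventionally quoted as "above 10⁴" and the
boundary case is unobservable in practice, so inclusivity is a
documentation choice, not a scientific one.

The critical intake IR\* = BMDL₁₀·10⁶·BW / (threshold·TEQ) is the exact
inverse of the chain; the tests verify MOE(EDI(IR\*)) = threshold to 1e−9
relative error over random positive parameters.

Intake scenarios (mean and 95th percentile, g/day, per commodity) are
configuration inputs. The national consumption records that a real
assessment would use are not published at this granularity, so the shipped
scenario table is an illustrative synthetic stand-in; MOE columns computed
from it characterize the pipeline, not the real population.

## Synthetic-data generator

The generator produces every input the pipeline consumes, under the study
conditions of the reference survey: a 110-sample design (10 samples each of
6 spices and 5 herbs), the published calibration response lines per matrix
and compound, published per-level mean recoveries, and per-commodity ×
compound detection rates.

Concentrations follow a left-censored lognormal: detected with probability
`detect_prob` (from the published detection rates), and conditional on
detection drawn from Lognormal(µ, σ) truncated below at the LOQ via
inverse-CDF sampling. The lognormal family is the standard choice for trace
contaminants; only summary statistics are published, so the shape σ = 0.8
is a fixed package default in the typical range for food-contaminant data,
and the location µ is solved so that detect_prob × E[lognormal] matches the
published commodity mean (censored samples contribute zero to that mean).
Truncation at the LOQ is ignored in that inversion — adequate while the LOQ
sits in the lower tail, slightly biasing the generated mean upward when
censoring is heavy. Compounds are generated independently within a sample;
real PAH co-occurrence is positively correlated, so synthetic PAH4 sums are
less dispersed than real ones. Passing tests therefore demonstrate the
pipeline's arithmetic and its statistical calibration against a known
generating process, not distributional fidelity to any real market.

Intake draws come from a two-parameter lognormal solved from the scenario
pair (mean, P95): σ is the smaller root of σ²/2 − z₀.₉₅σ + log(P95/mean) = 0,
which exists iff P95/mean ≤ exp(z²/2) ≈ 3.87; scenario pairs outside that
range are rejected rather than approximated.

All generators take an explicit integer seed and touch no global state;
pipeline stages derive independent 31-bit seeds from the run seed through a
`SeedSequence`, so the full run is a pure function of its configuration.

## Numerical choices and degenerate inputs

* OLS via `scipy.stats.linregress`; R² computed from residuals so that a
  zero-variance response (exactly constant ratios) yields R² = 1 rather
  than NaN. Fewer than 3 points, or no concentration spread, are errors.
* RSD requires n ≥ 2 and a nonzero mean; violations raise rather than
  returning NaN.
* `log_sd = 0` survey cells are point masses; a point mass below the LOQ
  with positive detection probability is rejected as contradictory.
* Quartile ties and short vectors follow numpy's linear-interpolation
  quantile exactly; a brute-force order-statistic oracle in the tests pins
  the convention.
* Report CSVs carry units in every numeric column name and are written at
  full float precision, so bit-identical reruns are a meaningful check.

## Problem sizes

The test suite and the acceptance script use n = 10⁴ samples per cell for
Monte-Carlo detection-rate recovery (3-binomial-SE tolerance), 2 × 10⁵
draws for intake-quantile recovery (±2%), 1 000 random parameter draws for
the MOE round-trip identity, and the 110-sample demo survey for the
end-to-end run — sizes at which the binomial and quantile standard errors
are comfortably inside the asserted tolerances.

## Known limitations

* Substitution-by-zero censoring biases means and medians downward; no
  likelihood-based imputation is offered.
* Point-estimate exposure only: two intake scenarios, one body weight, no
  full-distribution or age-stratified assessment, no uncertainty intervals
  on MOE.
* The published per-commodity MOE columns depend on unpublished consumption
  data and cannot be reproduced; the package verifies the chain's algebra
  (round-trip identity, monotonicity) instead.
* The aggregate column of the reference summary table is reproducible from
  the printed compound means to ±0.01 µg/kg for 10 of 11 commodities; one
  (basil) differs by 0.028 because the published cell was computed from
  unrounded means.
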