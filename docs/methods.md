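# Methods

## Measurement model

Each biopsy yields ddPCR copy numbers for four marker genes. Two ratios
summarize the tissue state: the stromal ratio *PLA2G2A*/*DIO2* (strength of
the decidual reaction) and the uNK ratio *ITGAD*/*CD160* (expansion of
immunotolerant KIR⁺ uNK subsets). Both ratios shift strongly with the day of
the biopsy relative to the LH surge, so all inference is conditional on the
LH day (6–10; samples outside the calibrated range are skipped with a
warning rather than extrapolated).

Ratios are computed from raw copy numbers and fitted on the raw ratio scale.
For each (ratio, LH day) cell, two candidate families are fitted by maximum
likelihood — gamma (shape/scale, via `scipy.stats.gamma.fit` with location
pinned at zero, which solves the digamma shape equation internally) and
log-normal (mean/sd of log ratios, the exact MLE) — and the family with the
smaller Cramér–von Mises statistic

W² = 1/(12n) + Σᵢ (F(x₍ᵢ₎) − (2i−1)/(2n))²

is selected, both CDFs being evaluated on the same raw ratios so the two W²
values are directly comparable. Ties break toward log-normal, the natural
family for a ratio of log-scaled quantities. The family is selected per
(ratio, day) cell independently. Gene copies and hormone levels (progesterone,
estradiol, TSH) are fitted as normal distributions of their log10 values
(ML variance, i.e. the 1/n estimator).

A sample's percentile is 100·F̂(ratio) under its day's selected family only
(no model averaging). Quartile bins are [0,25) → Q1, [25,50) → Q2,
[50,75) → Q3, [75,100] → Q4; the binary states use strict inequalities —
*stalled* means percentile < 25, *heightened* > 75 — so an exact 25.0 is Q2
and not stalled. Because any fitted CDF is a monotone transform, percentiles
preserve within-day ranks exactly; the fitted family only matters for the
calibration of the percentile scale itself, which the probability-integral-
transform (PIT) tests check directly.

## Synthetic cohorts

The generator's defaults are the study conditions: cohorts of 779 biopsies
uniformly spread over LH+6..10; cross-trait latent correlation 0.377 (which a
Gaussian copula maps to a Spearman rank correlation of
(6/π)·asin(0.377/2) = 0.362); intercycle latent correlation of the stromal
trait 0.62 (bivariate-normal orthant probability at Φ⁻¹(0.25) gives a 55.0%
recurrence of the lowest-quartile state); paired cohorts of 316 subjects;
prospective outcome cohorts with a quartile exposure arm (prevalence 25%)
and live-birth probabilities 0.438 (stalled) vs 0.600, or 0.6961 (strong
uNK) vs 0.500 — arm odds ratios 0.52 and 2.29.

Mechanics: a sample's latent pair (z_s, z_u) is bivariate standard normal
with correlation ρ_cross; u = Φ(z) is uniform, and the ratio is the inverse
CDF of that day's configured family at u. The denominator gene is drawn
log-normally per day and the numerator is defined as ratio × denominator, so
the ratio is exact by construction and the PIT oracle (evaluating the *true*
generating CDF at the ratio) recovers the latent uniform exactly — the
independent oracle used throughout the tests. In paired cohorts the two
cycle-specific stromal latents are bivariate normal with correlation
ρ_cycle, while the uNK latents are drawn independently for every cycle: the
first biopsy's uNK state carries no information about the second's, and
coupling uNK to the persistent stromal trait would leak an indirect
intercycle uNK correlation of ρ²_cross·ρ_cycle. The within-cycle
cross-correlation is therefore zero in paired cohorts, a deliberate
simplification — paired analyses treat the two ratios separately.

Per-day distribution parameters (families alternating between gamma and
log-normal across days, medians drifting upward with day for both ratios)
were chosen once as a realistic luteal-phase trajectory that exercises both
families during calibration. Prior-loss categories 0,1,2,3,≥4 default to a
recurrent-miscarriage-clinic mix (0.15/0.20/0.25/0.20/0.20), independent of
the latent trait; an optional proportional-odds tilt (`prior_loss_beta`)
enriches low stromal traits in higher-loss groups for enrichment
experiments. Among miscarriages, 30% are karyotyped aneuploid and 25%
euploid by default (roughly the karyotyping yield of a prospective clinical
cohort); outcome cohorts also carry their generator-assigned exposure flag
as an `exposed` column so odds-ratio recovery can be measured without
scoring-side misclassification.

A single symmetric Gaussian copula cannot simultaneously reproduce a 55%
low-quartile and a 36% high-quartile recurrence; `quartile_transition`
accepts a user-supplied 4×4 row-stochastic matrix for such asymmetric
dependence (no default is shipped). Replicate r of any multi-replicate
experiment uses seed + r; all randomness flows from the configured seed and
no stage touches global random state.

What the generator does *not* emulate: measurement error in ddPCR counts
(ratios are exact transforms of the latent), within-biopsy spatial
heterogeneity, day-estimation error in LH timing, covariate structure
(age, BMI, TSH) beyond the optional prior-loss link, and any non-Gaussian
tail dependence between traits or cycles. Passing tests therefore
demonstrate that the pipeline recovers the statistics of data satisfying its
own distributional assumptions, not that real cohorts satisfy them.

## Statistical machinery

- **One-versus-all 2×2 chi-square** per cell of the paired 4×4 table, with
  Yates continuity correction; when any expected count is below 5 the
  p-value falls back to the two-sided Fisher exact test.
- **Fisher exact test**, two-sided by the minimum-likelihood convention
  (the sum of all hypergeometric outcomes no more probable than the observed
  table), as implemented by `scipy.stats.fisher_exact`; verified in the
  suite against an exhaustive hypergeometric enumeration for every 2×2
  table with total ≤ 30. Bonferroni family size defaults to the 16 cells of
  one table (m = 4 per column is exposed as config); stratified analyses
  keep the family within each stratum. A cell whose observed count equals
  its expectation has direction "none" and is never significant.
- **Row-uniformity**: chi-square goodness of fit of each row's four counts
  against uniform expectation (df = 3).
- **Recurrence** of a state is the diagonal cell's share of its row — a
  conditional probability, undefined (NaN, flagged) for an empty row.
- **Odds ratios**: OR = ad/bc with the Woolf interval
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and a two-sided z-test on the log
  scale; a zero cell triggers the Haldane–Anscombe +0.5 correction on all
  cells, flagged in the result. Aneuploid exclusion removes subjects whose
  miscarriage is karyotyped aneuploid before tabulation. The forest output
  reports each quartile bin against all others, for both outcome codings
  (miscarriage risk and live-birth rate are the same tabulation).
- **Kruskal–Wallis** with tie correction (scipy), followed by Dunn's
  pairwise z tests on pooled mid-ranks with the standard tie term
  (Σ(t³−t))/(12(N−1)); Bonferroni adjustment by default, Holm as config.
  Dunn's test is implemented here directly since no installed package
  provides it. Non-significant pairs are summarized with compact letters
  (insert-and-absorb).
- **Pairwise frequency comparisons** across prior-loss groups use the same
  Yates chi-square with a Fisher fallback for small expectations, Bonferroni
  over the number of pairwise comparisons.

## Numerical choices and degenerate inputs

Minimum per-day calibration size is 20 (`min_n`); `--pool-adjacent` merges a
sparse day with its nearest neighbour instead of failing. Zero or missing
copy numbers exclude a sample from that ratio's calibration (logged) and
from scoring (skip log); an optional pseudocount is deliberately not applied
by default. Log-sd below 1e-6 raises a degenerate-data error. Percentiles
are kept at full precision in all stored JSON/CSV output and rounded only
for display (one decimal for percentages). The reference model serializes to
versioned JSON and round-trips to bit-identical scores.

## Problem sizes

The verification suite scales simulations to what the statistics require:
Spearman recovery uses 50 cohorts of 779 samples, recurrence recovery 200
paired cohorts of 316 pairs against one n=2,000 reference model,
false-positive control 1,000 null paired cohorts, and odds-ratio recovery 50
cohorts of 20,000 subjects; PIT uniformity uses ≥2,000 samples per LH day.
These sizes keep Monte-Carlo error comfortably below the tolerances being
asserted (e.g. the standard error of the mean recurrence over 200×316 pairs
is ≈0.4 percentage points against a ±2-point band).

## Known limitations

The percentile model assumes the reference cohort is itself representative
for each LH day — there is no covariate adjustment (age, BMI, TSH) inside
the reference model, by design. The intercycle copula is symmetric, so the
heightened-state recurrence equals the stalled-state recurrence by
construction; matching distinct printed recurrences for the two tails
requires the asymmetric transition-matrix mode with user-supplied values.
Exact-boundary percentiles (exactly 25.0 or 75.0) follow the strict printed
inequalities; measurement noise makes exact boundaries measure-zero events
in practice, but binned summaries of heavily rounded inputs could be
sensitive to the convention.
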