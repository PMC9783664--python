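# Methods

This note documents the statistical model behind each stage of `methylrad`,
the tunable parameters with their defaults, the design choices made where
the design was genuinely open, and the known limitations — in particular
what the synthetic-data tests do and do not demonstrate about real data.

## Data model and coordinates

Per-CpG methylation evidence is a pair of integer matrices (coverage,
methylated counts) over sites × samples, with sites identified by chromosome
and the 1-based position of the cytosine (the Bismark coverage convention,
strand-collapsed; no +/− merging is performed). Reading several coverage
files unions their sites; a site absent from a sample gets coverage 0 so
that retention decisions live entirely in the coverage filter. DMRs are
stored 1-based inclusive over their member CpGs and written as BED6+
(0-based half-open) with area in the score column.

## Global 5mC% (ELISA)

The standard curve is zero-intercept least squares of blank-subtracted OD
against ng of 5mC standard: slope = Σaᵢyᵢ / Σaᵢ², where yᵢ = ODᵢ − OD_NC.
Forcing the intercept to zero follows from the quantification formula
itself, which subtracts the negative-control OD — the curve must pass
through the blank. Sample content is

    5mC% = (OD_sample − OD_NC) / (slope × DNA_ng) × 100 ,

linear in the blank-subtracted OD and inversely proportional to slope and
input DNA (100 ng is a default, configurable per sample). Negative values
are reported with a warning, never clamped: they are informative about
plate noise. Group summaries use mean ± SEM (n−1 sd); a single-member group
reports SEM 0 with an explicit flag rather than NaN.

## Smoothing

Each sample's raw fractions mᵢ/cᵢ are smoothed with a weighted local
polynomial of degree 2 evaluated at the centre CpG. The window at a site is
the smallest symmetric radius R ≥ `half_width` (default 500 bp) containing
at least `min_cpgs` (default 20) CpGs; the radius grows to the next nearest
CpG until the count is met or the chromosome is exhausted (flagged). Weights
are tricube in distance scaled by R, times coverage, so uncovered sites
contribute nothing but still receive a fitted value — retention is the
coverage filter's job, not the smoother's. Fits are clamped to [0, 1].

Numerical details: the normal equations are solved per site with weights
normalised to sum 1; a determinant below 10⁻¹⁰ (or a window with zero total
coverage) triggers a fallback to the coverage-weighted window mean, or to
the sample's global coverage-weighted mean fraction when the whole window
is uncovered, both flagged. Windows never cross chromosome boundaries
(genomic distance is undefined across them). "Window of 500" is interpreted
as a 500 bp *radius*, exposed as a parameter since total-width readings of
that phrase exist.

Smoothing ignores group labels; this is what makes it valid to smooth once
and reuse the profile across all label permutations.

## t statistics, thresholds and regions

For two groups (≥2 samples each; the sign convention is irradiated −
sham):

    t = (mean₁ − mean₂) / (sd_pool · sqrt(1/n₁ + 1/n₂)) ,

where sd_pool is the pooled within-group sd of smoothed values, floored at
its genome-wide 75th percentile (parameter `sd_floor_quantile`) so
near-constant sites cannot produce unbounded t. Sites are first filtered to
those with ≥`min_cov` (10) coverage in ≥`min_samples` (3) samples *in each
group* — the per-group reading keeps both group means estimable; an
"overall" reading is the documented alternative.

Thresholds are the empirical 1st/99th percentiles (type-7 linear
interpolation, stated for bit-reproducibility) of the observed t
distribution. A DMR is a maximal run of consecutive retained CpGs with
t ≥ cutoff_high (hyper) or t ≤ cutoff_low (hypo), membership inclusive at
the cutoff, broken at gaps > `max_gap` (300 bp) and discarded below
`min_cpgs_region` (3) CpGs — the gap/size defaults follow the conventions
of the region finders this procedure descends from and are configurable.
Each region carries n_cpgs, span, mean smoothed difference, and the area
statistic Σ|t|, which is additive over any partition of the region.

## Permutation inference

Null areas come from balanced relabellings of the samples: assignments are
drawn uniformly (with replacement across iterations) from the C(n₁+n₂, n₁)−1
non-identity splits — 69 for a 4-vs-4 design — or enumerated exhaustively on
request. Each permutation recomputes t statistics **and** its own quantile
cutoffs (the cutoffs are defined as quantiles of the permutation's t
distribution; recomputing them preserves exchangeability between observed
and null region calling), then re-calls regions; all resulting areas are
pooled genome-wide. A DMR's p-value is the plain fraction of pooled null
areas ≥ its observed area — ties count against the DMR, "exceeding" read
conservatively as ≥ — so p can be exactly 0; an add-one correction
(b+1)/(n+1) is available behind a flag, default off, fidelity to the plain
fraction first. BH adjustment is the step-up rule q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j
capped at 1. (BH is deliberately *not* asserted to be idempotent: adjusted
vectors re-adjusted can inflate, e.g. [0.1, 0.9] → [0.2, 0.9] → [0.4, 0.9].)

Randomness is counter-based: permutation i derives its generator from
(seed, i), so the sequence is reproducible independently of execution
order. Validation candidates ("top" DMRs) require p < 0.05 *and* |mean
smoothed difference| > 0.25; the difference is computed on smoothed values,
consistent with the t statistics, with the raw-fraction alternative left as
a switch.

## Annotation

Each DMR gets the gene minimising the gap distance on its chromosome:
0 for intersecting intervals, otherwise the coordinate difference
(downstream start − upstream end + 1 in half-open coordinates), matching
closest-interval tooling; bookended intervals are 1 bp apart, so distance 0
holds exactly when the intervals intersect. Ties break deterministically to
the leftmost gene start and all tied names are reported. Strand affects
only the upstream/downstream label (the DMR's position in the gene's
orientation), never the choice of gene.

## ΔΔCT expression

ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts a control term
and log2 fold change = −ΔΔCt (efficiency fixed at 2.0; the "log2^−ΔΔCT"
notation found in kit write-ups is read as the log2 fold change, matching
log-fold-change axes). Two control terms are implemented because cohort
designs differ: the control-group *mean* ΔCt for unpaired animal designs
(control-vs-control then yields exactly 0 by construction), or the same
subject's baseline-visit ΔCt for longitudinal patient designs (V1/V2 vs
V0); the mode is explicit. Technical replicates are averaged, with a
warning above a 0.5-cycle spread. The reference-stability ranking is a
deliberately simple variance decomposition — sqrt(pooled within-group +
between-group variance of each candidate's deviation from the candidate-
panel mean), ascending — adequate for ranking a small candidate panel; it
is not a full stability-model implementation and is documented as plumbing.

## Association

Pearson r with the two-sided p from t = r·sqrt((n−2)/(1−r²)) on n−2 df
(n ≥ 3). Correlation tables pair subjects strictly by id — ids present in
only one table raise an error rather than silently shrinking n — and report
per-correlation p-values without multiplicity adjustment (a BH column is
optional), plus |r| alongside the signed r when absolute reporting is
requested. MHD stratification splits at 2.5 Gy with equality assigned to
the low-dose stratum (the threshold phrasing "higher or lower" leaves
equality open; the choice is a documented constant).

## Synthetic data

The bisulfite generator emulates a targeted-capture two-group design:

- CpG positions: geometric gaps (mean 100 bp, minimum 2 bp) — a renewal
  process approximating island/shore-enriched capture spacing.
- Baseline profile: logistic of a latent Ornstein–Uhlenbeck walk (sd 1.5,
  correlation length 2000 bp, clamped to [0.02, 0.98]). The sd/length were
  chosen once to give smooth bimodal island-like profiles spanning low and
  high methylation; the clamp avoids degenerate all-0/all-1 sites that
  break variance estimation.
- Planted DMRs: default 20 intervals of 10–30 CpGs shifted by ±0.3,
  separated by ≥5 CpGs, and placed only where the baseline absorbs the full
  shift without hitting the clamp — the recorded ground-truth effect size
  is the effect actually planted.
- Counts: per-sample fractions Beta-distributed around the group profile
  (overdispersion ρ = 0.05; real replicates are overdispersed relative to
  binomial), coverage Poisson(λ = 30, a realistic capture depth that
  satisfies the 10× filter at most sites), methylated ~ Binomial.

Companion generators invert the ELISA formula exactly at zero noise, plant
known log2 fold changes in Ct tables (reference Ct constant at 20), and
draw outcomes from the conditional normal achieving a chosen population
correlation. Recovery scoring matches called to planted intervals
one-to-one, greedily by descending interval Jaccard at a 0.5 threshold.

What the synthetic data does *not* emulate: cell-composition heterogeneity
of blood, conversion-efficiency artefacts, coverage biases that correlate
with methylation, SNP/copy-number confounding, and chromosome-scale
structure. Passing recovery tests therefore demonstrates the correctness of
the estimators and machinery, not field performance on real cohorts.

## Known limitations

**Quantile thresholds under dense signal.** The 1st/99th-percentile
thresholds admit, by construction, about 1% of retained CpGs per tail as
region members. When differential CpGs are rare (the regime this design
assumes, and the regime of genome-scale data) the thresholds sit just above
the null and regions recover planted intervals well. When planted signal is
dense — the default synthetic configuration plants ~8% of CpGs — the
thresholds land *inside* the true-signal t distribution, and calls become
conservative fragments of the strongest regions: interval-level sensitivity
at Jaccard ≥ 0.5 is then structurally capped near (callable 2%)/(planted
8% × 0.5) ≈ 0.5 regardless of implementation, and measured values are far
lower because fragments also fail the Jaccard bar. The acceptance script
reports this honestly (sensitivity and one-to-one FDR near 0/1 at the dense
default, while every significant call lies inside a true planted interval —
`dmr_significant_true_overlap_fraction` = 1). Region-level conclusions from
this caller should treat calls as cores of differential regions, not their
full extents.

**Other limitations.** Two-group comparisons only (no covariates, no
multi-dose joint models); CpG context only; the permutation null is pooled
genome-wide rather than matched per region; the reference-stability ranking
is simplified; amplification efficiency is fixed at 2.0.

## Problem sizes used in the checks

The recovery and null-control checks run 1 chromosome × 500 kb (~5,000
CpGs), 4 vs 4 samples, 200 permutations, over a handful of seeds; the
machinery checks (BH, permutation p-values, label uniformity) use exact
small-n enumeration or 10⁴ draws. These sizes were chosen as the smallest
at which the asserted properties are statistically stable.
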