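# Methods

## Data model and conventions

Internally every coordinate is 1-based inclusive, matching cytosine
reports; BED input/output converts at the I/O boundary
(`start_internal = start_bed + 1`). Symmetric-CpG strand collapse is on by
default: the minus-strand cytosine at position p is summed into its
plus-strand partner at p−1 (an unpartnered minus-strand CpG still becomes
a plus-strand locus at p−1). Collapse never changes genome-wide count
totals. Cohort assembly takes the union of loci across samples with N=0
fill, so coverage filters — not file contents — decide which loci enter
each analysis. Context filtering keeps CG rows only by default; CHG/CHH
rows are dropped with a logged count.

## Per-CpG age regression (aDMPs)

Percent methylation (100·M/N, undefined where N=0) is regressed per CpG
on age plus covariates by OLS, categoricals expanded to drop-first
indicators. Uncovered samples are dropped listwise per locus
(`n_used` records the remainder); loci with fewer than (terms+2) usable
samples, zero-variance response, or a rank-deficient post-deletion design
are flagged and excluded from the Benjamini–Hochberg correction. The
two-sided p-value for β_age uses df = n_used − params. The source method
describes a mixed model with one observation per subject; with no
repeated structure no random effect is identifiable, so the estimator
here is OLS with fixed covariates — numerically identical in that design
— and repeated-measures users should group observations upstream.
Loci are solved in batches grouped by missingness pattern (one matrix
decomposition per pattern), which makes the 5000-locus suites run in
seconds.

aDMP calling uses raw p < α (default 0.05), as in the emulated analysis;
q-values are reported alongside for users who prefer FDR thresholds.

## Sliding-window analysis (SWAN)

Window width 10 years, step 1 year, per-center BH at q < 0.05, minimum 5
subjects per window. Valid centers keep both windows inside the observed
age range (for ages 22–83 this yields centers ≈33–72; edge centers would
only report artefacts of empty age ranges). Two grouping modes:

* `adjacent` (default): [c−w, c) vs [c, c+w) — the most literal reading
  of "compared to the neighboring 10-year window". Its contrast measures
  *change across c*: a symmetric age-window deviation (elevated for
  |age−center| ≤ h) produces profile peaks at the deviation's **edges**
  (onset and offset), and is exactly zero at the deviation's center when
  both windows contain equal elevated fractions. The test suite pins this
  behaviour.
* `centered`: |age−c| ≤ w/2 vs all other subjects (the inside-vs-outside
  variant of the cited sliding-window method). This mode peaks at the
  **center** of an age-localised deviation and is the mode used for the
  planted-wave recovery checks.

The per-feature statistic is the group-indicator OLS t, computed in
closed form; it is algebraically the pooled equal-variance two-sample
t-test, and the suite verifies agreement to 1e-10 against an independent
implementation. Degenerate features: zero pooled variance with nonzero
mean difference → p=0 (perfect separation); fully constant feature → t=0,
p=1; a window dropping below the subject minimum after missing-value
removal → missing at that center. Optional covariate adjustment fits the
full linear model per feature (slow path, off by default since the
emulated analysis states none).

## Smoothed two-group region calling (aDMRs)

Loci are clustered per chromosome with a maximum inter-locus gap of 10^8
bp (chromosome boundaries always split). Per sample and locus, a weighted
least-squares quadratic of raw fraction on position is fitted over the
smallest symmetric-in-count window holding ≥ `min_loci` loci and spanning
≥ `min_width` bp (defaults 70 and 1000 at genome scale), truncated at
cluster boundaries; weights are tricube in scaled distance times read
coverage, so uncovered loci (weight 0) receive imputed fitted values.
Fitted values are clipped to [0,1]. A quadratic profile inside one window
is reproduced exactly (any positive weights), constants are always
preserved, and the smoother is equivariant to adding a constant before
clipping. Clusters (or samples) with fewer than 3 covered loci fall back
to the coverage-weighted cluster mean and are flagged.

The per-locus statistic is

    t_j = (mean_old − mean_young) / max(sd_j, floor)

with sd_j the young-group standard deviation of smoothed values scaled by
sqrt(1/n_y + 1/n_o) (two-sample unit consistency; configurable off), and
the floor the 0.75 quantile of all sd_j. The floor is a denominator
regularisation: smoothing makes some young-group variances collapse
toward zero, and without a floor those loci dominate the tails. Local
mean correction subtracts a running mean of t over ±50 loci within the
cluster (window shrinking at edges), removing large-scale baseline drift;
it is identity when disabled. Regions are maximal runs of consecutive
same-sign loci with |t| ≥ 4.6 and gaps ≤300 bp within one cluster; each
run reports CpG count, direction (hyper = old above young), the mean
smoothed difference, and the area statistic (sum of corrected t). No
minimum CpG count or mean-difference filter is applied by default; both
are available as parameters.

Group splitting at a threshold age supports both conventions seen in
practice: inclusive (old ⟺ age ≥ threshold) and exclusive
(old ⟺ age > threshold).

**Scale note.** The 70-loci default presumes genome-scale CpG density
(~26M CpGs), where 70 loci span a few kilobases. Synthetic genomes here
carry 10³–10⁴ CpGs over megabases, so the test and reproduction suites
scale the window to 15 loci while keeping the 1000-bp physical minimum —
preserving the smoothing *scale* the parameters encode rather than their
literal count. Swapping young/old labels negates every t's sign and swaps
hyper/hypo; magnitudes can differ because the variance stays anchored on
whichever group is currently labelled young.

## Annotation and enrichment

Gene linkage: a feature overlapping any transcript span is intragenic
(distance 0); otherwise any strand-aware TSS within 200 bp (two-sided)
yields a TSS-proximal link with signed distance, negative upstream by
strand. One link per qualifying feature–gene pair is emitted; summary
counting gives intragenic precedence. Island context: distance to the
nearest merged island on the same chromosome; island at 0, shore at
1–2000 bp (inclusive), shelf at 2001–4000 bp, open sea beyond (shelf
bounds follow common usage; the emulated analysis states only the 2-kb
shore). Reported percentages round half away from zero. The three-set
overlap counts all seven exclusive Venn regions over (chrom, pos) keys,
with the regional set materialised as all analysis loci falling inside
any called region. Over-representation is the upper-tail hypergeometric
p = P(X ≥ k) per gene set (sets intersected with the declared universe),
BH-corrected across sets — a database-free replacement for external
pathway services.

## Synthetic cohorts

The generator emulates the study design the analyses assume: ~40 subjects
with ages evenly spread over 22–83 (uniform draws by default, an explicit
age list for designs that need guaranteed coverage of an age range),
~10× Poisson read depth, CpGs clustered in islands (low baseline, ~0.15)
against a sparse open sea (high baseline, ~0.85) with per-locus logit
jitter (sd 0.5), plus an unmethylated lambda spike-in (0.5% apparent
methylation) for conversion QC. Genome layout depends only on structural
parameters (its own fixed `genome_seed`), so replicates that differ in
`seed` share coordinates and differ in counts — letting suites average
over count noise at fixed geometry.

For subject s and locus j the true fraction is

    p_sj = expit( a_j + b_j·(age_s − age_mid) + wave_j(age_s)
                  + step_j(age_s) + batch_sj + ε_sj ),   ε ~ N(0, σ²_logit)

with N_sj ~ Poisson(coverage) (zeros kept: the missing-data path must be
exercised) and M_sj ~ Binomial(N_sj, p_sj). The subject-level logit noise
makes counts beta-binomial-like overdispersed. Planted effects are
specified in percentage points at the locus baseline and converted to
logit offsets exact at the baseline (offset = logit(p₀+δ/100) − logit(p₀),
targets clamped into (0.001, 0.999) with a log record); linear slopes are
linearised at the baseline, accurate to ~1% over the cohort span for
slopes ≤0.3 points/year. Default per-subject logit noise 0.3 gives
realistic ~7–8 point between-subject spread at intermediate baselines.

What the generator does **not** emulate: read-level artefacts (m-bias,
conversion failure at the read level), correlated coverage along the
genome, genuine batch structure in methylation calls (batch is a knob,
default off), CpG-SNP confounding, or cell-composition mixtures. Passing
suites therefore demonstrate correctness of the statistics under the
stated noise model, not robustness to those real-data pathologies.

## Numerical choices

BH adjustment delegates to statsmodels (`fdr_bh`) with NaN propagation
(missing tests don't count toward m). Hypergeometric tails come from
scipy; the one-sided Fisher test is used only as an independent oracle in
tests. Smoothing solves 3×3 normal equations batched across samples per
locus (positions centred and scaled to the window radius for
conditioning); singular systems fall back to per-sample weighted least
squares, then to weighted means. Tricube weights are floored at 1e-6 so
boundary loci keep the design full-rank — harmless to polynomial
exactness, which holds for any positive weights. The regression's exact-
fit edge (zero residual, nonzero slope) reports p=0 at machine precision.

## Problem sizes in the shipped suites

Test and reproduction runs use 500–10,000 CpGs, 10–40 subjects and
10–30× coverage — sizes where every statistic is exercised end-to-end in
seconds per scenario and Monte-Carlo checks (type-I error 0.05 ± 0.01 on
5000 null CpGs; ≥95% of 20 null genomes with zero called regions) remain
tight. The planted-DMR recovery fixture places a dense 10-CpG island in a
2-kb-spaced open sea, the geometry in which a 10-CpG region occurs in
real data, so the 300-bp run-splitting rule delimits the called region
at the island rather than at smoothing spill-over.
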