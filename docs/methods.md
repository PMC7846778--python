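# Methods

This note documents the statistical models implemented in `cgimeth`, the
defaults and what they mean, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## CGI methylation from bisulfite counts

A CpG count table holds strand-combined methylated/unmethylated read
counts per CpG (1-based positions; the on-disk Bismark-coverage dialect is
1-based inclusive and converted at the boundary, all interval arithmetic
is 0-based half-open BED convention internally). CGI methylation is the
coverage-weighted mean beta: pooled methylated reads over pooled total
reads across CpGs inside the island. Only CpGs with coverage ≥ 10 in
*every* sample of an analysis enter it (inclusive boundary); islands with
no usable CpGs are reported missing, never zero.

**Differential gain.** Per CGI the 2×2 table of pooled (methylated,
unmethylated) counts by condition is tested with a two-sided Fisher's
exact test; p-values are BH-adjusted across all tested CGIs, and a gainer
requires q < 0.05 and a beta gain ≥ 0.20. The table construction from
*pooled* counts is a design choice (consistent with weighted-mean =
pooled ratio); per-CpG test combination would be an alternative and is
not implemented. Pooling across replicate libraries, where present,
happens at the count level before testing. The ≥ 0.20 comparison carries
a 1e-12 epsilon so the inclusive boundary survives binary rounding of
beta differences.

The two-sided exact p is computed with a vectorised log-gamma
hypergeometric (mass of all tables at the observed margins no more likely
than the observed one, with the usual 1 + 1e-7 tie tolerance). It agrees
with `scipy.stats.fisher_exact` to ~1e-13 but tests hundreds of thousands
of islands per second, which the per-call scipy interface cannot. The
one-off one-sided enrichment tests (peak overlap, term enrichment) go
through `scipy.stats.fisher_exact` directly.

Array-style beta matrices are called methylated at beta ≥ 0.3 (inclusive);
missing betas are excluded from frequency denominators. Bisulfite-PCR
clone summaries drop clones with ≥ 25% error positions (inclusive) and
average over read positions only. The global mass-spectrometry 5mC level
is 100 × area(5mC)/area(G).

## Re-methylation kinetics

After 5-aza-dC demethylation, each CGI's mean methylation m(c, t) is
normalised by its own day-0 value; only CGIs with day-0 methylation
strictly above 0.5 are analysed (below that, the ratio is dominated by
noise and the island was not methylated to begin with). Normalised values
may exceed 1 and are not clipped — raw means are divided as-is.

Two linear mixed models are fitted to the normalised methylation at
timepoints in [3, 22] days inclusive:

- null (outgrowth): common slope in time, random intercept per CGI;
- alternative: random intercept *and* random slope per CGI, modelled as
  correlated bivariate Gaussian effects (a flag switches to independent
  effects, df 1).

Both are fitted by **maximum likelihood** (not REML) so the
likelihood-ratio comparison is valid. The fit profiles out the fixed
effects and the residual variance analytically and optimises the
log-Cholesky-parametrised relative covariance of the random effects with
Nelder–Mead from several starts; groups sharing a timepoint pattern share
one marginal covariance inverse, so a 200-CGI × 6-timepoint dataset fits
in ~0.1 s. A unit test cross-checks the maximised log-likelihoods against
`statsmodels` MixedLM on the same data (the in-package optimiser attains
at least as high a likelihood; agreement ~1e-4 on the null model).

The LRT statistic is referred to chi-square with df = 2 (slope variance +
intercept–slope covariance). Because the slope variance sits on the
boundary of its parameter space under the null, this reference is
conservative; simulated null data reject at ~1–3% at nominal α = 0.05.
Non-convergence raises with diagnostics; a single CGI is refused (random
effects unidentifiable).

Per-CGI recovery rates are ordinary least-squares slopes of each island's
normalised trajectory over days 3–22; the slope is the fraction of day-0
methylation recovered per day. Islands with fewer than two distinct
in-range timepoints are skipped and flagged. Group contrasts (e.g.
H3K36me3-marked vs other islands) use two-sided Wilcoxon rank-sum tests
with medians reported.

## ChIP quantification and spike-in scaling

Fragment counting over islands or windows is any-overlap (≥ 1 bp); the
window builder centres contiguous fixed-width windows (default 250 bp) on
the island midpoint — odd counts centre the middle window on the
midpoint, even counts put the midpoint on the central boundary — and
truncates at position 0. Whether a minimum overlap fraction should be
required is unstated upstream; any-overlap is the documented assumption.

Normalised signal adds a 0.5 offset to ChIP and input counts (so empty
input windows cannot divide by zero), scales each to counts per 10⁷
mapped reads, and divides ChIP by input. Regions covered in no sample
should be removed first (`covered_regions`). The per-10⁷ denominator is
each run's total mapped reads (target + spike-in); this is configurable
in principle and documented because the convention is not fixed by the
formula alone.

The spike-in scaling factor for sample n against a reference is

    S_n = (dRPTM_ChIP-n / dRPTM_ChIP-ref) / (dRPTM_IN-n / dRPTM_IN-ref)

with dRPTM = spike-in reads per 10⁷ mapped reads of that run; the input
ratio cancels differences in spike-in mixing proportion between samples.
S_ref is exactly 1. **Direction:** a sample with globally higher target
occupancy captures *fewer* spike-in reads per 10⁷, so S_n < 1 for that
sample and its signal must be multiplied by 1/S_n
(`RxScaling.correction`) to land on the reference scale;
`apply_rx_scaling` is a plain multiplier and the pipeline passes the
correction. Replicate means are taken after scaling. With the total-reads
denominator the implied fold change 1/S of a true k-fold global change is
k·(M_T + M_D)/(k·M_T + M_D) — for the default spike-in fraction 1/21
(20:1 target:spike-in cell ratio) a 2-fold change reads out as ~1.95,
a ~2.5% spike-dilution bias that vanishes as the spike fraction shrinks.

Decile association ranks islands by a signal, splits them into 10 equally
sized groups (remainder spread over the lowest groups) for display
summaries, and computes Spearman's rho over islands, not groups. The
histone-mark linear model z-scores predictors so coefficients are
comparable, reports coefficient/SE/t/p, and flags condition numbers above
1e6. Heatmap display ranges run from the minimum to the 90% quantile
(linear interpolation between order statistics) without truncating the
values themselves. qPCR percent-of-input adjusts the input Ct to 100%
chromatin by subtracting log₂(1/input_fraction) cycles and assumes
amplification efficiency 2; "adjusted to 100%" is interpreted as exactly
that cycle shift.

## Term enrichment and Wang similarity

Gene annotations are closed over ontology ancestors (is_a / part_of
edges, DAG enforced); a CGI carries a term if any assigned gene carries
it. Enrichment of a target CGI set against the background is a one-sided
Fisher's exact test per term, BH-corrected across tested terms, with
terms carried by fewer than 10 background CGIs excluded before testing.
Contingency counts are at the CGI level, not the gene level.

Wang similarity assigns S-values to a term's ancestor closure — S = 1 at
the term itself, decaying by the edge weight (defaults 0.8 for is_a, 0.6
for part_of, the method's original parameterisation) along the best
path — and scores two terms by the summed S-values of common ancestors
over total S-value mass. Collapsing visits significant terms in ascending
q (ties broken by term id): each unclaimed term seeds a group and is
kept, and any unclaimed term with similarity strictly above 0.7 to the
seed joins and is dropped. Greedy-by-q grouping is a documented choice;
single-linkage clustering would be an alternative.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, seed) and emit truth tables.

- **CpG counts** (`simulate_cpg_counts`): per-CpG methylated counts are
  Binomial(coverage, beta of the island in that condition) with Poisson
  coverage truncated at ≥ 1 (mean 30 by default); gainers get
  beta + gain in condition B. Defaults — 500 islands, 8 CpGs each,
  baseline beta 0.1, 20% gainers of size 0.5 — give pooled depths of
  ~240 reads per island per condition. Not emulated: bisulfite
  conversion error, CpG-density structure, fragment-level sampling and
  coverage correlation between neighbouring CpGs. Consequently passing
  tests show the *caller's* operating characteristics under clean
  binomial sampling, not robustness to conversion artefacts.
- **Time courses** (`simulate_timecourse`): trajectories follow
  m0·(residual + slope·(t − 3)) with Gaussian observation noise on the
  beta scale (sd 0.02 default), clipped to [0, 1]. Day 0 is noise-free:
  it is the normalisation anchor, and noise there would leak a spurious
  per-CGI scale factor into normalised trajectories, violating the
  outgrowth-null structure the regime is meant to embody. Under the null
  regime all islands share the residual level (0.5 — total methylation
  roughly halves by day 3) and slope; under the heterogeneous regime
  slopes are Gaussian with configurable sd (the Gaussian choice mirrors
  the random-slope model class, not a measured distribution). The default
  mean rate 0.025/day restores ~97% of day-0 methylation by day 22
  (recovery is essentially complete within ~3 weeks) and keeps raw
  trajectories below the beta ceiling, so clipping never distorts the
  null. Default grid {0, 3, 6, 10, 14, 18, 22} days; only day 0, 3, 6
  and 22 are anchored by the experimental design, the rest are plumbing
  and configurable.
- **ChIP-Rx** (`simulate_chip_experiment`): per-island signal is
  Gamma(2, 1); libraries are multinomial reads over islands proportional
  to signal (inputs uniform), with a binomial spike-in split at mass
  fraction 1/21 and a configurable global fold change on one sample.
  Truth records the closed-form expected scaling factor. Counts stand in
  for alignments; no fragment-length, mappability or GC structure.
- **Ontology** (`simulate_ontology`): a single-root random DAG (every
  term reachable from the root) with 1–3 direct terms per gene and one
  planted term annotated to a known gene subset for enrichment recovery.

## Problem sizes and calibration checks

The acceptance script and test suite use: 500 islands at coverage 30 for
gain-caller sensitivity/specificity (both ≥ 0.98 expected: a 0.5 gain at
~240 pooled reads is a > 8σ Fisher signal, and a spurious ≥ 0.20 delta
under the null at baseline 0.1 is itself a > 8σ event); 200 null and 100
heterogeneous time-course replicates of 200 islands each for type-I error
and power of the heterogeneity LRT; 500 islands for slope recovery
(Pearson r ≥ 0.9 at noise sd 0.02; exact to ~1e-12 without noise); 10⁶
reads for spike-in fold-change recovery (within 5%); 1000 islands for
rank association; an exhaustive sweep of all 2×2 tables with total ≤ 40
plus 3000 randomised tables with totals to 200 against an integer-
arithmetic enumeration oracle for the exact test. The end-to-end
pipeline at 500 islands completes in well under a minute on one CPU, and
reruns with an identical config and seed are byte-identical.

## Known limitations

- The heterogeneity LRT uses the naive df-2 chi-square reference rather
  than the boundary mixture; it is conservative, never anticonservative.
- The pooled-count Fisher construction treats reads as independent;
  overdispersion between CpGs within an island (present in real RRBS) is
  neither simulated nor modelled.
- The spike-in simulation's truth is exact only under the implemented
  dRPTM denominator convention; with a large spike-in fraction the
  dilution bias of 1/S as a fold-change estimate grows.
- Interval operations ignore strand throughout, which is correct for the
  strand-combined methylation and unstranded island/peak inputs this
  package targets, but makes it unsuitable for strand-resolved assays.
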