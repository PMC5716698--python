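# Methods

## Scope and model

`cpgdiff` implements a two-arm differential methylation workflow for
probe-level beta-value matrices: probe filtering, beta→M transformation,
an empirical-Bayes moderated two-group contrast per probe, BH false
discovery control, intersection of a paired discovery arm with an
unpaired validation arm, gene-level DMR calling, category and overlap
enrichment, hierarchical clustering, and LINE-1 / X-chromosome
comparisons. The package operates downstream of array preprocessing: it
assumes normalized beta-values as input and does not model raw
two-channel intensities, background correction, or probe-type chemistry
(those require channel-level data).

### Moderated contrast

M-values M = log2(β′/(1−β′)), with β′ clipped to [ε, 1−ε], are modelled
per probe. The paired design is fitted as a one-sample location model on
within-pair tumor−control differences; for the mean contrast this is
algebraically equivalent to a blocked two-group design (the residual df
bookkeeping differs, which matters only at very small n). The unpaired
design is a two-group pooled-variance contrast.

Variance moderation follows the standard hierarchical model: observed
s²_g with d_g residual df, a scaled-inverse-chi-square prior with
hyperparameters (d₀, s₀²) estimated by moment matching on
z_g = log s²_g using digamma/trigamma identities, the trigamma inverse
solved by Newton iteration. Two estimator properties worth knowing:

* If the method-of-moments excess variance of z_g is non-positive, d₀ is
  infinite and every posterior variance equals s₀². With identical s²_g
  across probes, s₀² = s²·(d/2)/exp(ψ(d/2)) — the chi-square log-bias
  correction, not s² itself; the factor tends to 1 as d grows. This is
  the behavior of the standard estimator, asserted exactly in the tests.
* Probes with s²_g = 0 (constant differences) enter the log-moment fit
  through a guard of 10⁻⁸ times the smallest positive variance, so they
  are shrunk rather than producing infinite statistics.

With shrinkage disabled (d₀ = 0) the statistic reduces to the classical
paired / two-sample t, which the tests verify to 10⁻¹⁰.

Effect sizes are reported on the beta scale (Δβ = mean β difference,
pairwise under the paired design) because the DMR threshold is stated in
methylation-percentage units. Direction (hypo/hyper) is assigned from
the sign of Δβ; in rare near-zero cases the M-scale coefficient can
disagree in sign (the β→M map is probe-specifically nonlinear), which is
resolved in favor of Δβ and logged.

### BH adjustment

Step-up: sort ascending, q_(i) = min_{j≥i} p_(j)·m/j capped at 1,
original order restored. Implemented in-package (it is part of the
calling contract) and cross-checked in tests against both a brute-force
threshold-enumeration oracle and statsmodels.

### Intersection and DMR rule

Common DMSs are probes significant in both arms; direction-discordant
probes are dropped by default (and counted). The overlap fraction is
referenced to the discovery arm, reported as a whole percent. The DMR
rule operates at gene level: a gene qualifies per direction when it
carries ≥ `min_sites` (default 3) same-direction common DMSs with at
least one |Δβ| ≥ `min_effect` (default 0.20). Grouping is by gene, not
by (gene, category) — regions in practice mix promoter and body probes
of one gene — with a strict per-category mode behind a flag. Direction
partitioning precedes counting, so one gene can yield at most one hypo
and one hyper region. Intergenic sites do not participate. Probes
annotated to several genes support each of them.

### Enrichment

Category tables test direction × category membership per category as a
2×2 chi-square against the rest of the class. Counts are association
counts: a probe contributes once per distinct gene-relation category it
carries (column totals therefore exceed unique probe counts);
island relation is single-valued. The chi-square is uncorrected by
default with a Yates option — published tables of this kind are
ambiguous about the variant, so both are exposed.

Overlap enrichment draws B sets of |query| probes uniformly without
replacement from the background and counts reference overlap per draw;
the one-sided empirical p uses the +1 correction so it is never zero and
is floored at 1/(B+1). The null overlap is exactly hypergeometric, which
the tests exploit as an independent oracle (null mean within 3 SE;
empirical p uniform under a random query). Draws are vectorized
(chunked argpartition over uniform matrices) so B = 10,000 is cheap.
Gene-set enrichment is a one-sided hypergeometric upper tail per set
with BH across sets, and an eligibility rule that sets overlapping the
query in fewer than `min_genes` (default 5) genes are never called
significant regardless of p.

### Clustering and group tests

Samples are clustered on 1 − Pearson correlation between profiles
(complete linkage for methylation, average exposed for expression-style
use). Bootstrap support resamples features with replacement and counts
how often each original internal-node sample bipartition recurs —
bipartition recurrence, not exact topology, since tree heights are
unstable. The two-cluster cut is scored against provided labels by
majority labeling, with label ties counted as misplaced (conservative).
A zero-variance sample is an error naming the sample, because its
correlation is undefined.

Notch intervals are median ± 1.57·IQR/√n with type-7 (linearly
interpolated) quartiles — stated explicitly because the half-width
depends on the quantile convention. LINE-1 comparisons use the Student
t-test (equal variances) per CpG position by default, Welch behind a
flag, and Kruskal–Wallis with tie correction for ≥3 groups; constant
data yield statistic 0 / p 1 by convention, and no multiplicity
correction is applied across the four positions (raw p-values are the
reporting convention for these panels).

## Synthetic-data generator

The generator emulates the structure of a paired tumor/normal 450K
study, not any particular dataset:

* **Annotation** — probes across chr1..22 (chrX optional) with sorted
  positions; genes as runs of 1–8 consecutive probes (60% of runs share
  one gene-relation category, so ≥3-probe same-category blocks exist by
  construction); ~25% intergenic runs; island relations sampled with an
  open-sea majority; ~1% SNP-flagged and ~0.7% non-CpG probes.
* **Cohort** — baseline beta per probe is bimodal by island relation
  (islands low via Beta(1.5, 8.5), open sea high via Beta(8, 2), shores
  and shelves intermediate). Defaults follow the emulated study design:
  8 tumor/control pairs plus 11 unpaired tumors and 3 extra controls;
  58% of spikes hypomethylated; mean spike |Δβ| 0.20; tumor-wide shift
  −0.02; M-scale noise SD 0.10 and within-pair correlation 0.5 are
  realism choices (no noise model is published for such cohorts).
  Effects are injected on the M scale and transformed back, clipping at
  10⁻⁶, so betas stay in range; pair effects are shared random
  intercepts (SD = noise·√(r/(1−r))); spiked probes receive mid-range
  baselines (U(0.35, 0.65)) so the configured effect always fits in
  [0, 1]. DMR-block members share a (gene, category) run, one direction
  per block, every member at least at the configured effect size.
  Spiked probes avoid SNP/non-CpG/sex-chromosome probes so spikes
  survive filtering. One global seed fans out to per-component
  substreams (SeedSequence spawn keys), so adding a component does not
  perturb the others.
* **Reference catalog** — round(concordance·n_spiked) spiked probes with
  true directions plus `extra_n` random background probes with random
  directions, emulating an external DMS list that shares signal with
  the cohort.
* **LINE-1 tables** — four percent-methylation columns per sample,
  Gaussian around per-CpG base levels (SD 2pp), with a group shift on
  CpG1 only by default (−2pp for tumors), mirroring the
  first-position-only pattern such panels show.

What the generator does **not** emulate: probe-type (I/II) chemistry
bias, batch structure, cell-type heterogeneity, copy-number aberrations,
spatial correlation of betas along the genome beyond gene-block spikes,
and realistic detection-p failure patterns. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to array artifacts.

### Null and recovery conditions

Calibration simulations (p-value uniformity, BH false-positive control,
spike-recovery FDR) set the tumor-wide shift to 0: a global shift makes
every probe truly differential, so "false positive" is only defined
without it. The spec of those conditions is: 8 pairs + 11 vs 11, 200
spikes at |Δβ| = 0.25, M-noise 0.08 for recovery; no spikes, default
noise for nulls. Problem sizes are chosen as the package's own test
scale: 1,000 probes for null calibration (small-m estimation noise in
s₀² inflates family-wise error below ~500 probes), 4,000 probes × 50
replicates for recovery.

## Numerical choices

* ε = 10⁻³ for the M transform (boundary handling is unstated in the
  conventions this follows; round trip is exact on [ε, 1−ε]).
* Filter precedence detection → SNP → non-CpG → sex chromosomes keeps
  report counts disjoint. The detection rule is a per-probe failure
  fraction (default: any sample with detection p > 0.05 removes the
  probe); iterative row/column schemes are deliberately simplified to a
  reproducible single pass.
* Covariate residualization is an exact OLS projection (with intercept);
  rank-deficient covariate matrices are rejected rather than
  pseudo-inverted. A PCA screen reports correlations of leading
  components with covariates in lieu of surrogate-variable estimation.
* BED export converts 1-based manifest positions to 0-based half-open
  single-base intervals; scores are round(1000·|Δβ|) capped at 1000.
* Missing betas are NA, excluded per probe from means and fits (the
  residual df then vary per probe, which the moderation handles).

## Known limitations

* The DMR rule is annotation-driven (gene-level), not distance-based;
  bump-hunting-style smoothing over genomic windows is out of scope.
* Surrogate-variable estimation is not implemented; explicit covariates
  plus the PCA screen are the supported adjustment path.
* The paired fit assumes complete pairs; incomplete pairs are rejected
  rather than imputed.
* Only two-group contrasts are supported (no multi-factor designs or
  continuous phenotypes).
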