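# Methods

This note records the models and procedures the package implements, the
conventions chosen where several were defensible, and what the synthetic
fixtures do and do not establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open. BLAST tabular coordinates
(1-based inclusive, with start > end on the minus strand) are normalised on
read and only there, so interval algebra downstream is free of off-by-one
cases. Depth input is fixed to the 3-column samtools-depth dialect
(contig, 1-based position, depth); rows for zero-depth positions may be
absent, and a dense table gives bit-identical summaries to its sparse
equivalent. `mdepth` is the mean depth over covered bases; because the VRU
weight multiplies it by the covered fraction, the product equals total
mapped bases over contig length, so the "mean over covered bases" and
"mean over the whole contig" readings of mean depth give the same weight.

## Unphaging

A viral-versus-bacterial alignment hit marks an excisable region when its
percent identity is ≥ 70 and the aligned fraction of the **viral query**
(alignment length / query length) is ≥ 0.70. Both thresholds are
inclusive; the coverage denominator is the viral genome because the
question asked is "is this viral genome present on this bacterial contig",
and a subject-length denominator would make short prophages on long
contigs undetectable. Overlapping and book-ended intervals are unioned
per contig before excision so that multiply-hit regions are removed once.
Residual bacterial fragments shorter than 2,000 bp (the pipeline's global
contig floor, configurable) are dropped and their base count logged;
per-contig accounting is exact: fragment + prophage + dropped bases equal
the input length. A contig with no qualifying hit passes through
unchanged, which also makes unphaging idempotent — re-running on an
already-cleaned database removes nothing.

## Mining

The length floor keeps contigs of exactly 2,000 bp ("shorter than" is
read strictly). Predicted prophage regions from multiple detectors are
merged and excised into candidate phage contigs (`<parent>_pp<k>`); the
host-side fragments remain visible to the bacterial filter, and excised
candidates survive that filter even when their parent is flagged
bacterial. The consensus call is the conjunction of the primary-score
threshold (PhaMer-like score ≥ 0.9, inclusive) and the strict score-sum
agreement (PhaMer-like + MetaPhaPred-like > 1). A missing secondary
score contributes 0; a missing primary score is an error, since its
threshold is mandatory. The two auxiliary classifiers
(DeepVirFinder-like, VirSorter2-like) are recorded in the decision trace
but do not change the verdict; a `dvf_rescue` switch (default off) lets
both auxiliaries jointly rescue a rejected contig, kept off because the
agreement rule exists to remove false positives. The decision function is
monotone in both primary scores, which the property tests exploit.

## Dereplication

Identity and coverage come from the best local alignment (match +1,
mismatch −1, gap open −2, gap extend −0.5) of the shorter sequence
against the longer, on whichever strand scores higher — phage contigs are
unoriented. Identity is matched bases over aligned columns; coverage is
the aligned span of the shorter sequence over its length, so exact
containment scores 1.0 and the statistic is symmetric. Clustering is
greedy longest-first (ties broken lexically by contig ID): a contig joins
the first representative it matches at ≥ 0.98 identity and ≥ 0.85
coverage, else founds a cluster. One exact alignment engine is used at
all scales; all-versus-all dereplication beyond ~10⁴ contigs is out of
scope. Correctness is checked against a brute-force all-pairs oracle on
instances of ≤ 30 sequences of 300–500 bp drawn from 4 seed genomes at
≤ 1% divergence — sizes chosen so the exhaustive oracle stays cheap while
still exercising multi-cluster structure.

## Annotation post-processing

All rejection thresholds are inclusive (score ≥ 0.7 passes; host
confidence ≥ 95 with ≥ 1 shared protein). Filtered calls are nulled, not
deleted, so every contig keeps a row and downstream quantification still
counts it. Two taxonomy sources merge by agreement: where both assign
different families the call is voided (a `primary_priority` policy is
available). Bin-level propagation assigns a bin's single non-null family
to all members; bins with two or more distinct families are discarded —
meaning their members' family assignments are voided while the contigs
themselves survive, since quantification is annotation-agnostic. The
discarded-bin fraction is reported over all bins. Host merging prefers
the alignment-based source; read-classification calls fill gaps, and
genus conflicts are resolved toward the alignment source with a flag.

## Quantification

Per sample, `VRU_i = w_i / Σ w` with `w_i = mdepth_i · coverage_i`. A
sample with no signal yields an all-zero vector and a flag rather than an
exception (downstream analyses can then exclude it explicitly). Groups
are keyed by (family, lifestyle, host genus) with nulls mapped to an
explicit `unclassified` level, so grouping preserves row sums exactly and
VRUs remain a composition. Presence is strictly `VRU > 0`.

## Statistics

* **Shannon diversity** in natural log, computed on normalised family
  proportions.
* **Log transform**: `ln(x + c)` with `c` defaulting to half the smallest
  nonzero table entry — small enough not to compress real signal, large
  enough to keep zeros finite; configurable.
* **Pearson distance**: `d = 1 − r` between sample profiles, in [0, 2].
  Zero-variance profiles are an error naming the sample.
* **PCoA**: classical scaling via the doubly centred Gower matrix and a
  symmetric eigendecomposition. 1 − r is not Euclidean, so negative
  eigenvalues occur; they are reported but excluded from the
  proportion-explained denominator, and coordinates span positive axes
  only.
* **PERMANOVA**: sequential (type-I) sums of squares in term order,
  computed as traces of projector differences against the Gower matrix;
  F compares each term's mean square with the residual. P-values permute
  raw sample labels (999 by default), counting the observed statistic:
  `p = (1 + #{F* ≥ F}) / (1 + n_perm)`, reproducible bit-for-bit under a
  seed. Factors confounded with sample identity (one sample per level)
  are rejected. Negative sequential SS for null terms is expected with
  semimetric distances.
* **Gaussian LMM** on log abundance: REML fit of a random-intercept model
  per infant (statsmodels MixedLM), Wald p-values; singular or
  non-converged fits are flagged honestly, never raised.
* **Binomial GLMM** on presence: marginal maximum likelihood with the
  per-group 1-D Gaussian integrals evaluated by 21-node Gauss–Hermite
  quadrature; standard errors from the numerically differentiated Hessian
  at the optimum. This is a genuine ML fit (cross-checked against
  lme4::glmer with adaptive quadrature, agreeing to ≲ 0.05 on all
  coefficients), not a quasi-likelihood or variational approximation.
  Apparent separation (|β| beyond 15 on the logit scale or a
  non-invertible Hessian) triggers a flagged ridge-penalised refit rather
  than silent divergence. Per-family screens adjust p-values by
  Benjamini–Hochberg within each model term, and families present or
  absent in fewer than 3 samples are skipped as unidentifiable.

## Synthetic fixtures

The generators plant a known truth for every stage. Databases are i.i.d.
uniform nucleotide backbones with viral segments inserted at recorded
coordinates and matching alignment hits written at configurable identity
and query coverage — so threshold behaviour is testable by construction
(hits written at 60% identity must produce zero excisions at the 70%
threshold). Classifier scores draw from Beta(8, 1) for true phages and
Beta(1, 8) for non-phages, with per-tool label-flip rates; a degenerate
mode emits exactly 1.0/0.0 so consensus recovery is deterministic at zero
error. Cohorts mirror the study design in miniature: two age windows
(~40% of samples in the younger), ~17% cesarean-born infants, ~27% of
samples phage-enriched, delivery fixed per infant, and per-infant random
intercepts N(0, 0.5²) with residual SD 0.5 on the log scale. The default
cohort is 8 infants × 10 samples so the full suite runs in minutes;
recovery and calibration checks use 40 infants × 10 samples, where Wald
intervals attain near-nominal coverage.

What passing these tests shows: the implementations compute their stated
definitions exactly (oracle equivalence), and the statistical layer is
calibrated when its model assumptions hold. What they do not show:
robustness to real metagenomic structure — compositional zero inflation
beyond the simulated sparsity, phylogenetic sequence similarity between
distinct phages (the uniform-nucleotide model makes unrelated sequences
more distinguishable than real ones), classifier errors correlated across
tools, or unbalanced longitudinal designs with informative missingness.
Conclusions about real cohorts still require the usual sensitivity
analyses.

## Numerical conventions

Distance matrices are symmetrised to remove float noise and validated
(zero diagonal, non-negativity). VRU row sums hold to ≤ 1e-12; grouping
preserves them exactly because it only ever adds disjoint components.
Greedy dereplication and unphaging have fully deterministic output orders
(length-then-ID and contig-then-position respectively), and every
generator is a pure function of its seed.
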