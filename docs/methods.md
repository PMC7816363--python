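# Methods

This note documents the models and procedures implemented in `gutdx`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Abundance profiles

The pipeline's currency is the feature abundance matrix (FAM): samples ×
taxa relative abundances, each row closed to sum 1 (tolerance 1e-9 at
validation, 1e-12 per entry for aggregation checks). Raw inputs are
aligned-read counts with per-feature reference lengths; the count rate
`c/L` corrects for feature length and the per-sample closure corrects for
sequencing depth. The two corrections commute under closure, which is why
closure was chosen as the depth correction: any per-sample rescaling of
counts leaves the profile unchanged. Samples with no aligned reads are
rejected rather than imputed — a silent all-zero row would corrupt every
downstream rank statistic.

Genus-rank profiles (16S mode) are the sums of member-strain abundances
under a strain→genus map; aggregation conserves per-sample mass exactly.
WGS mode and 16S mode differ only in feature rank and model bundle.

## Three-step feature selection

Defaults (all strict inequalities): abundance floor 1e-6, rank-sum alpha
0.01, edge alpha 0.05, strong-correlation cutoff |ρ| > 0.4, iteration
stops below 3 nodes. No multiple-testing correction is applied, by
design: the filter is a screening step feeding a redundancy collapse and
a cross-validated model, not an inferential endpoint.

Rank-sum p-values are exact when both groups have ≤ 10 samples — a
shift-DP enumeration over doubled midranks, with the two-sided p defined
as the permutation probability of a rank sum at least as far from its
null mean as observed (correct under arbitrary ties) — and otherwise use
the tie- and continuity-corrected normal approximation. A feature
constant across all samples has p = 1 by convention.

Co-occurrence edges are Spearman correlations computed as Pearson on
midranks, with two-sided p from the t-approximation on n − 2 degrees of
freedom; only validated edges (p < 0.05) enter the graph. An optional
permutation p-value mode (count and seed in `SelectionConfig`) is exposed
for small feature sets. Constant features have undefined correlations and
stay isolated, with a logged warning.

Hub extraction is a greedy loop: select the node of maximal degree — ties
broken by larger Σ|ρ| over incident validated edges (summed with `fsum`
in id order, so the tie-break is reproducible), then by lexicographic
feature id — remove it together with neighbours joined by a validated
edge with |ρ| > 0.4, and repeat while ≥ 3 nodes remain. Two decisions
were open and are resolved as follows: degree-0 nodes are selectable (an
uncorrelated but significant feature is a signal, not redundancy; it
removes only itself), and leftover nodes at termination are *not*
selected, which preserves the invariant that no two selected hubs share a
strong validated edge. Consequently a survivor set of size S yields at
most S − 2 hubs; benchmarks that measure marker recovery must provide
survivor sets comfortably above the stopping size.

## Grouped cross-validation and evaluation

Folds are assigned at the individual level: within each class,
individuals are shuffled with the given seed and dealt round-robin across
folds ordered by current occupancy, so per-class fold sizes differ by at
most one and all samples of an individual travel together. Individuals
whose samples carry conflicting labels are rejected. Feature selection
and the decision threshold are derived from each fold's training samples
only; the per-fold train/test individual sets are recorded so tests can
audit the absence of leakage.

AUC is the Mann–Whitney probability (ties counted half) and AP the
step-interpolated area under the precision–recall curve, both via
scikit-learn; independent brute-force oracles in the test suite verify
the pair-counting and step-sum identities. Ties in AP are grouped at a
single threshold — the standard convention — rather than broken
arbitrarily by sort order. Accuracy is measured at the per-fold default
threshold (positive prevalence of that fold's training labels), with
score ≥ threshold calling the positive class so printed two-decimal
cutoffs behave as inclusive bounds.

Backends: LightGBM (default), logistic regression, random forest,
gradient boosting, SVM, all seeded and overridable via params. The
LightGBM defaults are sized for cohort-scale data (tens to a few hundred
samples): `min_child_samples=5`, 100 trees, `num_leaves=31`, single
thread with `force_row_wise` and `deterministic` for bit-reproducible
fits. Upstream library defaults assume thousands of rows and degenerate
to a constant (split-free) model on data this size.

If the three-step selection returns no hubs inside a fold or stage fit —
typical for null cohorts, where the differential filter removes
everything — the stage falls back to the abundance-filtered feature set
with a logged warning, so that null data still yields scores (near-chance
AUC) instead of an error.

## Marker-set shrinkage

Significance scores estimate "the error-rate increment caused by removing
a feature" by column permutation in the held-out fold of a grouped
five-fold CV (3 repeats by default), floored at zero — k× cheaper than
retraining without the feature and standard practice; a model-internal
`gain` importance mode is exposed as an alternative. Columns are fitted
in sorted-id order and the permutation stream is keyed by feature id, so
scores do not depend on the caller's column order. The waiting-list curve
then runs, for every prefix of the descending ranking, 5 independent
grouped five-fold CVs (round seeds spawned from the master seed) on just
those features; the chosen size is the smallest prefix attaining the
maximal mean AUC — ties go to the smaller marker set, since a smaller
reference database is cheaper to align against.

## Two-stage prediction

Stage 1 scores a profile for IBD; score ≥ threshold routes it to stage 2
(UC vs CD), otherwise the call is Health and stage 2 is never evaluated.
Model features absent from a query profile are imputed as 0 (an
undetected taxon), with a warning listing them; a data-type mismatch
between profile and bundle is an error. Alignment hit tables (12-column
tabular format) are reduced to best-hit counts per query — highest bit
score, ties to the lexicographically first subject — before
normalization. Scores are raw backend probabilities, uncalibrated.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
via logistic-normal compositions: per feature a baseline log-abundance
(sd `base_sigma`, default 1.5 — heavy-tailed compositions), per
individual a latent vector adding block factors and individual noise
(sd `individual_sigma`, default 1.0), per sample fresh noise (sd
`noise_dispersion`, default 0.3), then exponentiation and closure.
Correlated blocks share a latent factor whose loading is chosen through
the bivariate-normal identity ρ_S = (6/π)·asin(c/2) so the induced
Spearman correlation matches the target. Planted differential features
are shifted by `log_effect_size` in the case class (IBD for stage 1, CD
for stage 2) and reported as ground truth. Resequenced individuals reuse
their latent vector with fresh sample noise, reproducing the
within-individual similarity that grouped CV exists to guard against.

Closure couples features: boosting planted features in cases deflates
every other feature there. This is genuine compositional behaviour, and
it means "null" features in a planted cohort carry a weak, real group
signal through the shared denominator. The planted-marker benchmark
(`planted-markers`: 300 individuals, 20% resequenced, 50 features, 5
planted at 1.5 log units ≈ 4.5× fold change) exploits this deliberately:
the effect is strong for rank-sum detection yet keeps pooled
between-marker |ρ| below the 0.4 collapse cutoff, and the closure-borne
survivors give the hub iteration enough nodes that the planted markers
are never lost to the stopping rule.

The study-shaped preset (`paper-shape`) reproduces the cohort arithmetic
exactly: 318 individuals of whom 47 relative-health individuals
contribute one sample each and 78 of the remaining 271 are sequenced
twice — 396 samples, shrinking to 349 (201 Health, 127 UC, 21 CD) after
exclusion. The paper-level totals do not determine the per-class split of
individuals; the preset uses the largest-remainder apportionment
(156/99/16 individuals with 45/28/5 resequenced), which reproduces every
printed count. Other presets: `tiny-separable` (40 samples, 20 features,
constructed so that *every* feature — boosted or closure-deflated —
separates the groups by several standard deviations, making the cascade's
CV AUC ≈ 1 whichever single representative the hub step keeps),
`tiny-null` (120 samples, no signal; sized so a five-fold mean AUC
concentrates near 0.5), and `tiny-cohort` (46 samples, three classes, for
end-to-end two-stage runs).

What passing tests on these cohorts do **not** show: robustness to real
sequencing artefacts (compositional zeros, variable depth, batch
effects), to taxonomic misassignment, or to covariate confounding — the
generator models none of these. Problem sizes throughout (≤ 360 samples,
≤ 1000 features in the calibration check) are the package's chosen
benchmark scale.

## Known limitations

- Stage-2 training needs ≥ 2 samples (in practice ≥ k individuals) per
  subtype; very small CD arms make the UC/CD module unstable, mirroring
  the clinical difficulty of that contrast.
- Permutation importance splits credit between duplicated informative
  features; redundancy upstream (hub selection) mitigates but does not
  eliminate this.
- Default thresholds assume the training prevalence is meaningful for the
  deployment population; scores are not calibrated probabilities.
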