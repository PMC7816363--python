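# gutdx

Two-stage classification of inflammatory bowel disease (IBD) from gut
microbiome taxonomic profiles.

The gut microbial community shifts markedly in IBD, and stool metagenomes
can be profiled non-invasively at strain (whole-genome sequencing) or
genus (16S rRNA) resolution. `gutdx` turns such profiles into a two-stage
diagnostic cascade: stage 1 decides Health vs IBD, and samples called IBD
are routed to stage 2, which separates the two major IBD subtypes,
ulcerative colitis (UC) and Crohn's disease (CD). It is aimed at
computational microbiologists building or evaluating microbiome-based
classifiers from case-control cohorts.

## Method

Inputs are feature abundance matrices (FAMs): samples × taxa tables of
relative abundances `x_{sf} ∈ [0, 1]` with `Σ_f x_{sf} = 1`, built from
aligned-read counts by length normalization and per-sample closure:

    x_{sf} = (c_{sf} / L_f) / Σ_g (c_{sg} / L_g)

For each binary contrast, marker taxa are chosen in three nested steps:

1. **Abundance floor** — keep features with relative abundance > 10⁻⁶ in
   at least one sample.
2. **Differential filter** — keep features with two-sided Wilcoxon
   rank-sum *P* < 0.01 between the groups (exact enumeration for small
   groups, tie-corrected normal approximation otherwise).
3. **Co-occurrence hub extraction** — build a network whose edges are
   validated Spearman correlations (*P* < 0.05); iteratively pick the most
   intensively connected node, remove it together with its strongly
   correlated neighbours (|ρ| > 0.4), and stop when fewer than three nodes
   remain. One representative survives per correlated cluster.

A gradient-boosted classifier (LightGBM by default; logistic regression,
random forest, gradient boosting and SVM backends are pluggable) is
trained per stage and evaluated with **individual-grouped, stratified
five-fold cross-validation**: repeatedly sequenced individuals contribute
correlated samples, so folds split individuals, never samples, and
feature selection is re-run inside each training fold. Performance is
reported as mean ROC AUC and mean average precision (AP), the latter
because the contrasts are unbalanced.

Before the final fit the marker set can be shrunk: each selected feature
receives a significance score — the cross-validated increase in error
rate when its held-out column is permuted — and a "waiting-list" curve
traces the cross-validated AUC of the top-*m* features for *m* = 1…K. The
final marker set is the smallest prefix attaining the maximal mean AUC.

Decision cutoffs default to the positive class's training prevalence
`N_pos / (N_pos + N_neg)`; in a study-shaped cohort (201 Health, 127 UC,
21 CD) this gives 0.42 for Health vs IBD and 0.14 for UC vs CD. A score
at or above the cutoff calls the positive class.

## Worked example

Everything runs on synthetic cohorts with known ground truth, so no
downloads are needed:

```bash
gutdx simulate --preset tiny-cohort --out cohort
gutdx train -t wgs --fam cohort/fam.tsv --manifest cohort/manifest.tsv \
    --seed 1 --out bundle
gutdx predict -t wgs --model bundle --fam cohort/fam.tsv --out pred
```

which prints

```
wrote 46 samples x 30 features to cohort
saved wgs bundle to bundle (stage1 threshold 0.59, stage2 threshold 0.33)
calls: {'Health': 20, 'UC': 17, 'CD': 9}
```

The thresholds are the training prevalences of IBD (27/46 ≈ 0.59) and CD
(9/27 ≈ 0.33) in this synthetic cohort, and every sample receives exactly
one call in {Health, UC, CD}; `pred/diagnosis.tsv` lists the per-sample
stage scores (the stage-2 column is empty for Health calls). Evaluation
and marker shrinkage work the same way:

```bash
gutdx evaluate -t wgs --fam cohort/fam.tsv --manifest cohort/manifest.tsv \
    --contrast uc_vs_cd --out eval.json
# uc_vs_cd: mean AUC 0.742, mean AP 0.573, mean accuracy 0.695
gutdx optimize -t wgs --fam cohort/fam.tsv --manifest cohort/manifest.tsv \
    --rounds 2 --out opt
# health_vs_ibd: optimal marker set has 2 features
```

The library mirrors the CLI one-to-one (`gutdx.select_features`,
`gutdx.cross_validate`, `gutdx.shrink_markers`,
`gutdx.predict_two_stage`, ...); see the module docstrings.

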