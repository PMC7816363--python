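"""Pre-training marker-set shrinkage.

After the three-step selection, each surviving feature receives a
significance score: the mean increase in the cross-validated error rate
(1 - accuracy at the default threshold) when that feature's column is
permuted in the held-out fold, destroying its information while keeping
its marginal distribution.  Features are ranked by score, and a
"waiting-list" curve is traced: for every prefix of the ranking, repeated
grouped five-fold cross-validations measure the mean AUC attainable with
only those features.  The final marker set is the smallest prefix that
attains the maximal mean AUC — a small reference database is cheaper to
align against, so ties go to fewer markers.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    cross_validate,
    grouped_stratified_kfold,
    positive_proba,
    stage_cohort,
    train_classifier,
)
from .profiles import FeatureAbundanceMatrix, SampleManifest

logger = logging.getLogger(__name__)


@dataclass
class SignificanceRanking:
    """Features ordered by descending score; ties broken by feature id."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ordered = sorted(self.entries, key=lambda e: (-e[1], e[0]))
        if [e[0] for e in ordered] != [e[0] for e in self.entries]:
            self.entries = ordered

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature_id", "score"])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tscore\n")
            for f, s in self.entries:
                fh.write(f"{f}\t{s!r}\n")


@dataclass
class FeatureCurve:
    """Cross-validated AUC as a function of ranking-prefix size."""

    prefix_sizes: list[int]
    round_aucs: list[list[float]]  # one list of per-round mean AUCs per size

    def __post_init__(self) -> None:
        if len(self.prefix_sizes) != len(self.round_aucs):
            raise ValueError("one AUC list per prefix size required")
        lengths = {len(r) for r in self.round_aucs}
        if len(lengths) > 1:
            raise ValueError("all prefix sizes need the same number of rounds")

    @property
    def mean_aucs(self) -> list[float]:
        return [float(np.mean(r)) for r in self.round_aucs]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for size, rounds in zip(self.prefix_sizes, self.round_aucs):
            for rnd, value in enumerate(rounds):
                rows.append((size, rnd, value))
        return pd.DataFrame(rows, columns=["prefix_size", "round", "auc"])

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write("prefix_size\tround\tauc\n")
            for size, rnd, value in frame.itertuples(index=False):
                fh.write(f"{size}\t{rnd}\t{value!r}\n")

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "prefix_sizes": self.prefix_sizes,
                    "round_aucs": self.round_aucs,
                    "mean_aucs": self.mean_aucs,
                },
                fh, indent=2,
            )


def significance_scores(
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    contrast: str = "health_vs_ibd",
    features: Sequence[str] | None = None,
    backend: str = "lightgbm",
    params: Mapping | None = None,
    seed: int = 0,
    repeats: int = 3,
    k: int = 5,
    mode: str = "permutation",
) -> SignificanceRanking:
    """Score each feature by the error-rate increment its removal causes.

    ``mode='permutation'`` (default) estimates removal by permuting the
    feature's held-out column within grouped k-fold CV; scores are floored
    at 0.  ``mode='gain'`` instead reports the fitted model's internal
    importance (tree gain, or |coefficient| for linear backends).
    """
    sub_fam, sub_manifest, task, positive = stage_cohort(fam, manifest, contrast)
    used = list(features) if features is not None else list(sub_fam.feature_ids)
    # canonical column order: tree builders tie-break on feature index, so
    # sorting makes the scores independent of the caller's column order
    used = sorted(used)
    X = sub_fam.data[used]

    if mode == "gain":
        module = train_classifier(
            X, task.values, positive, stage=contrast, data_type=sub_fam.data_type,
            backend=backend, params=dict(params or {}, importance_type="gain")
            if backend == "lightgbm" else params,
            seed=seed,
        )
        est = module.estimator
        if hasattr(est, "feature_importances_"):
            raw = np.asarray(est.feature_importances_, dtype=float)
        elif hasattr(est, "coef_"):
            raw = np.abs(np.asarray(est.coef_, dtype=float)).ravel()
        else:
            raise ValueError(f"backend {backend!r} exposes no internal importance")
        return SignificanceRanking(list(zip(used, raw)))
    if mode != "permutation":
        raise ValueError("mode must be 'permutation' or 'gain'")

    assignment = grouped_stratified_kfold(sub_manifest, k=k, seed=seed, labels=task)
    sample_folds = assignment.sample_folds(sub_manifest)
    increments = np.zeros(len(used))
    n_terms = 0
    for j in range(k):
        train_ids = list(sample_folds.index[sample_folds != j])
        test_ids = list(sample_folds.index[sample_folds == j])
        module = train_classifier(
            X.loc[train_ids], task.loc[train_ids].values, positive,
            stage=contrast, data_type=sub_fam.data_type, backend=backend,
            params=params, seed=seed,
        )
        X_test = X.loc[test_ids].values
        y_bin = (task.loc[test_ids].values == positive)
        thr = module.threshold

        def error_rate(matrix: np.ndarray) -> float:
            pos = positive_proba(module.estimator, matrix)
            return float(((pos >= thr) != y_bin).mean())

        baseline = error_rate(X_test)
        for fi, name in enumerate(used):
            # rng keyed by feature id, so scores do not depend on the
            # column order of the input matrix
            rng = np.random.default_rng([seed, j, zlib.crc32(name.encode())])
            for rep in range(repeats):
                perturbed = X_test.copy()
                perturbed[:, fi] = rng.permutation(perturbed[:, fi])
                increments[fi] += error_rate(perturbed) - baseline
        n_terms += repeats
    scores = np.maximum(increments / n_terms, 0.0)
    return SignificanceRanking(list(zip(used, scores)))


def incremental_curve(
    ranking: SignificanceRanking,
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    contrast: str = "health_vs_ibd",
    backend: str = "lightgbm",
    params: Mapping | None = None,
    rounds: int = 5,
    k: int = 5,
    seed: int = 0,
    max_prefix: int | None = None,
) -> FeatureCurve:
    """Waiting-list AUC trace: grow the marker set one feature at a time.

    For each prefix of the ranking, ``rounds`` independent grouped k-fold
    cross-validations (fold seeds derived from the master seed) are run
    using only those features; every per-round mean AUC is recorded.
    """
    if not ranking.entries:
        raise ValueError("ranking is empty")
    ordered = ranking.features
    if max_prefix is not None:
        ordered = ordered[:max_prefix]
    round_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(rounds)
    ]
    sizes = list(range(1, len(ordered) + 1))
    curve_aucs: list[list[float]] = []
    for m in sizes:
        prefix = ordered[:m]
        per_round = []
        for rseed in round_seeds:
            report = cross_validate(
                fam, manifest, contrast=contrast, k=k, seed=rseed,
                backend=backend, params=params, do_selection=False,
                features=prefix,
            )
            per_round.append(report.mean_auc)
        curve_aucs.append(per_round)
    return FeatureCurve(sizes, curve_aucs)


def select_optimal_prefix(curve: FeatureCurve) -> int:
    """Smallest prefix size attaining the maximal mean AUC."""
    means = curve.mean_aucs
    if not means:
        raise ValueError("curve is empty")
    best = max(means)
    for size, value in zip(curve.prefix_sizes, means):
        if value == best:
            return size
    raise AssertionError("unreachable")


def shrink_markers(
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    contrast: str = "health_vs_ibd",
    features: Sequence[str] | None = None,
    backend: str = "lightgbm",
    params: Mapping | None = None,
    seed: int = 0,
    repeats: int = 3,
    rounds: int = 5,
    k: int = 5,
) -> tuple[SignificanceRanking, FeatureCurve, list[str]]:
    """Rank features, trace the waiting-list curve, return the marker set."""
    ranking = significance_scores(
        fam, manifest, contrast=contrast, features=features, backend=backend,
        params=params, seed=seed, repeats=repeats, k=k,
    )
    curve = incremental_curve(
        ranking, fam, manifest, contrast=contrast, backend=backend,
        params=params, rounds=rounds, k=k, seed=seed,
    )
    best = select_optimal_prefix(curve)
    markers = ranking.features[:best]
    logger.info("marker shrinkage: %d -> %d features", len(ranking.entries), best)
    return ranking, curve, markers
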