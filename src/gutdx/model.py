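"""Classifier training and evaluation with individual-grouped cross-validation.

Some individuals in the cohort were sequenced twice; their repeated samples
are far more similar to each other than to other samples, so splitting at
the sample level would leak individual identity into the test folds and
inflate performance.  Folds are therefore assigned at the individual level,
stratified by class, and every sample of an individual travels with its
fold.

The decision cutoff on predicted scores defaults to the positive class's
training-set prevalence (e.g. 148/(148+201) = 0.42 for health vs IBD and
21/(21+127) = 0.14 for UC vs CD in the study cohort); a score greater than
or equal to the cutoff calls the positive class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC

from .profiles import FeatureAbundanceMatrix, SampleManifest
from .selection import SelectionConfig, select_features

logger = logging.getLogger(__name__)

BACKENDS = (
    "lightgbm",
    "logistic_regression",
    "random_forest",
    "gradient_boosting",
    "svm",
)

CONTRASTS = ("health_vs_ibd", "uc_vs_cd")
POSITIVE_CLASS = {"health_vs_ibd": "IBD", "uc_vs_cd": "CD"}

# Gradient-boosting defaults sized for cohort-scale microbiome studies
# (tens to a few hundred samples): upstream library defaults assume
# thousands of rows and refuse to split small nodes, which degenerates to a
# constant model on data this size.
_LIGHTGBM_DEFAULTS = dict(
    n_estimators=100,
    learning_rate=0.1,
    num_leaves=31,
    min_child_samples=5,
    n_jobs=1,
    force_row_wise=True,
    deterministic=True,
    verbosity=-1,
)


def make_estimator(backend: str, seed: int = 0, params: Mapping | None = None):
    """Instantiate a pluggable classifier backend with a fixed seed."""
    params = dict(params or {})
    if backend == "lightgbm":
        from lightgbm import LGBMClassifier

        kwargs = {**_LIGHTGBM_DEFAULTS, **params}
        return LGBMClassifier(random_state=seed, **kwargs)
    if backend == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if backend == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if backend == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if backend == "svm":
        return SVC(probability=True, random_state=seed, **params)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


# ---------------------------------------------------------------------------
# Grouped stratified folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Fold index per individual; all samples of an individual share a fold."""

    individual_to_fold: dict[str, int]
    k: int

    def sample_folds(self, manifest: SampleManifest) -> pd.Series:
        return pd.Series(
            {r.sample_id: self.individual_to_fold[r.individual_id]
             for r in manifest.records},
            name="fold",
        ).reindex(manifest.sample_ids)


def grouped_stratified_kfold(
    manifest: SampleManifest,
    k: int = 5,
    seed: int = 0,
    labels: Mapping[str, str] | None = None,
) -> FoldAssignment:
    """Assign individuals to k folds, stratified by individual-level class.

    ``labels`` optionally overrides the manifest labels at the sample level
    (e.g. to pool UC and CD into IBD for the first stage); an individual's
    class is the common class of its samples, and conflicting labels raise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels is None:
        ind_labels = manifest.individual_labels()
    else:
        ind_labels = {}
        for r in manifest.records:
            lab = labels[r.sample_id]
            prev = ind_labels.get(r.individual_id)
            if prev is not None and prev != lab:
                raise ValueError(
                    f"individual {r.individual_id!r} has conflicting labels "
                    f"{prev!r} and {lab!r}"
                )
            ind_labels[r.individual_id] = lab

    by_class: dict[str, list[str]] = {}
    for ind in manifest.individuals:
        by_class.setdefault(ind_labels[ind], []).append(ind)
    for cls, members in by_class.items():
        if len(members) < k:
            raise ValueError(
                f"class {cls!r} has {len(members)} individuals, fewer than k={k}"
            )

    rng = np.random.default_rng(seed)
    fold_counts = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        members = [members[i] for i in rng.permutation(len(members))]
        order = np.argsort(fold_counts, kind="stable")
        for i, ind in enumerate(members):
            fold = int(order[i % k])
            assignment[ind] = fold
            fold_counts[fold] += 1
    return FoldAssignment(assignment, k)


# ---------------------------------------------------------------------------
# Metrics and thresholds
# ---------------------------------------------------------------------------

def default_threshold(labels: Sequence, positive_class) -> float:
    """Positive-class training prevalence, used as the decision cutoff.

    The unrounded value is returned; round to two decimals for reporting.
    """
    labels = np.asarray(labels)
    n_pos = int((labels == positive_class).sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to derive a threshold")
    return n_pos / (n_pos + n_neg)


def auc(scores: Sequence[float], y_true: Sequence) -> float:
    """ROC AUC = P(score_pos > score_neg) + 0.5 * P(equal) over all pairs."""
    y = np.asarray(y_true, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def average_precision(scores: Sequence[float], y_true: Sequence) -> float:
    """Area under the precision-recall curve with step interpolation."""
    y = np.asarray(y_true, dtype=bool)
    if not y.any():
        raise ValueError("average precision needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def positive_proba(estimator, matrix: np.ndarray) -> np.ndarray:
    """Positive-class probability from a fitted binary estimator.

    Feeds the matrix back under the estimator's fitted feature names (some
    backends invent names even for array input and complain otherwise).
    """
    names = getattr(estimator, "feature_names_in_", None)
    if names is not None:
        matrix = pd.DataFrame(matrix, columns=list(names))
    proba = estimator.predict_proba(matrix)
    return proba[:, list(estimator.classes_).index(1)]


def _confusion(calls: np.ndarray, y: np.ndarray) -> dict[str, int]:
    return {
        "TP": int((calls & y).sum()),
        "FP": int((calls & ~y).sum()),
        "TN": int((~calls & ~y).sum()),
        "FN": int((~calls & y).sum()),
    }


# ---------------------------------------------------------------------------
# Trained stage modules
# ---------------------------------------------------------------------------

@dataclass
class TrainedModule:
    """A fitted stage classifier plus everything needed to apply it."""

    backend: str
    estimator: object = field(repr=False)
    feature_ids: list[str]
    positive_class: str
    threshold: float
    stage: str
    data_type: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class probability per sample; columns must match training."""
        if list(X.columns) != self.feature_ids:
            raise ValueError(
                "feature columns at prediction time must equal training order"
            )
        return positive_proba(self.estimator, X.values)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Thresholded call: score >= threshold -> positive class."""
        return self.scores(X) >= self.threshold

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "backend": self.backend,
            "feature_ids": self.feature_ids,
            "positive_class": self.positive_class,
            "threshold": self.threshold,
            "stage": self.stage,
            "data_type": self.data_type,
            "seed": self.seed,
            "params": self.params,
        }
        with open(directory / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        joblib.dump(self.estimator, directory / "model.joblib")

    @classmethod
    def load(cls, directory) -> "TrainedModule":
        directory = Path(directory)
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
        estimator = joblib.load(directory / "model.joblib")
        return cls(
            backend=meta["backend"],
            estimator=estimator,
            feature_ids=list(meta["feature_ids"]),
            positive_class=meta["positive_class"],
            threshold=float(meta["threshold"]),
            stage=meta["stage"],
            data_type=meta["data_type"],
            seed=int(meta["seed"]),
            params=dict(meta["params"]),
        )


def train_classifier(
    X: pd.DataFrame,
    labels: Sequence,
    positive_class: str,
    stage: str,
    data_type: str,
    backend: str = "lightgbm",
    params: Mapping | None = None,
    seed: int = 0,
    threshold: float | None = None,
) -> TrainedModule:
    """Fit a stage classifier; threshold defaults to training prevalence."""
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError(
            f"feature matrix has {len(X)} samples but {len(labels)} labels"
        )
    y = (labels == positive_class).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples per class to train")
    if threshold is None:
        threshold = default_threshold(labels, positive_class)
    estimator = make_estimator(backend, seed=seed, params=params)
    estimator.fit(X.values, y)
    return TrainedModule(
        backend=backend,
        estimator=estimator,
        feature_ids=list(X.columns),
        positive_class=positive_class,
        threshold=float(threshold),
        stage=stage,
        data_type=data_type,
        seed=seed,
        params=dict(params or {}),
    )


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold and aggregate AUC / AP / accuracy for one stage contrast."""

    k: int
    fold_auc: list[float]
    fold_ap: list[float]
    fold_accuracy: list[float]
    fold_threshold: list[float]
    fold_features: list[list[str]]
    fold_train_individuals: list[list[str]]
    fold_test_individuals: list[list[str]]
    confusion: dict[str, int]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_ap(self) -> float:
        return float(np.mean(self.fold_ap))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def pooled_accuracy(self) -> float:
        c = self.confusion
        total = sum(c.values())
        return (c["TP"] + c["TN"]) / total

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_auc": self.fold_auc,
            "fold_ap": self.fold_ap,
            "fold_accuracy": self.fold_accuracy,
            "fold_threshold": self.fold_threshold,
            "fold_features": self.fold_features,
            "confusion": self.confusion,
            "mean_auc": self.mean_auc,
            "mean_ap": self.mean_ap,
            "mean_accuracy": self.mean_accuracy,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def stage_cohort(
    fam: FeatureAbundanceMatrix, manifest: SampleManifest, contrast: str
) -> tuple[FeatureAbundanceMatrix, SampleManifest, pd.Series, str]:
    """Restrict a cohort to one stage contrast and derive its binary labels."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    labels = manifest.labels()
    if (labels == "RelativeHealth").any():
        raise ValueError(
            "manifest still contains RelativeHealth samples; apply "
            "exclude_relative_health first"
        )
    if contrast == "health_vs_ibd":
        task = labels.map(lambda l: "IBD" if l in ("UC", "CD") else "Health")
        sub_manifest = manifest
    else:
        keep = labels.isin(["UC", "CD"])
        sub_manifest = manifest.subset(labels.index[keep])
        task = labels[keep]
    sub_fam = fam.subset_samples(sub_manifest.sample_ids)
    return sub_fam, sub_manifest, task.reindex(sub_manifest.sample_ids), POSITIVE_CLASS[contrast]


def cross_validate(
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    contrast: str = "health_vs_ibd",
    k: int = 5,
    seed: int = 0,
    backend: str = "lightgbm",
    params: Mapping | None = None,
    selection_cfg: SelectionConfig | None = None,
    do_selection: bool = True,
    features: Sequence[str] | None = None,
) -> EvaluationReport:
    """Grouped k-fold evaluation with per-fold, training-only feature selection.

    Feature selection (and the decision threshold) are derived from each
    fold's training samples only; held-out individuals never influence them.
    Pass ``features`` (with ``do_selection=False``) to evaluate a fixed
    feature list, as the marker-shrinkage curve does.
    """
    sub_fam, sub_manifest, task, positive = stage_cohort(fam, manifest, contrast)
    assignment = grouped_stratified_kfold(sub_manifest, k=k, seed=seed, labels=task)
    sample_folds = assignment.sample_folds(sub_manifest)

    fold_auc, fold_ap, fold_acc, fold_thr = [], [], [], []
    fold_feats, fold_train_ind, fold_test_ind = [], [], []
    confusion = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    ind_of = {r.sample_id: r.individual_id for r in sub_manifest.records}

    for j in range(k):
        train_ids = list(sample_folds.index[sample_folds != j])
        test_ids = list(sample_folds.index[sample_folds == j])
        X_train = sub_fam.data.loc[train_ids]
        X_test = sub_fam.data.loc[test_ids]
        y_train = task.loc[train_ids]
        y_test = task.loc[test_ids]

        if features is not None:
            used = list(features)
        elif do_selection:
            result = select_features(X_train, y_train.values, selection_cfg)
            used = result.hubs
            if not used:
                logger.warning(
                    "fold %d: selection returned no hubs; falling back to the "
                    "abundance-filtered feature set (%d features)",
                    j, len(result.after_abundance),
                )
                used = result.after_abundance
        else:
            used = list(sub_fam.feature_ids)
        if not used:
            raise ValueError(f"fold {j}: no usable features")

        module = train_classifier(
            X_train[used], y_train.values, positive, stage=contrast,
            data_type=sub_fam.data_type, backend=backend, params=params, seed=seed,
        )
        scores = module.scores(X_test[used])
        y_bin = (y_test.values == positive)
        fold_auc.append(auc(scores, y_bin))
        fold_ap.append(average_precision(scores, y_bin))
        calls = scores >= module.threshold
        fold_acc.append(float((calls == y_bin).mean()))
        fold_thr.append(module.threshold)
        fold_feats.append(used)
        fold_train_ind.append(sorted({ind_of[s] for s in train_ids}))
        fold_test_ind.append(sorted({ind_of[s] for s in test_ids}))
        for key, val in _confusion(calls, y_bin).items():
            confusion[key] += val

    return EvaluationReport(
        k=k,
        fold_auc=fold_auc,
        fold_ap=fold_ap,
        fold_accuracy=fold_acc,
        fold_threshold=fold_thr,
        fold_features=fold_feats,
        fold_train_individuals=fold_train_ind,
        fold_test_individuals=fold_test_ind,
        confusion=confusion,
    )
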