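"""Two-stage diagnostic cascade: Health -> IBD -> {UC, CD}.

Stage 1 scores a query profile for IBD; a score at or above the stage-1
threshold routes the sample to stage 2, which decides UC vs CD.  Samples
called Health never reach stage 2.  WGS mode (strain-rank profiles) and
16S mode (genus-rank profiles) differ only in the model bundle and feature
rank; routing logic is shared.

Upstream alignment is out of scope: the adapter contract is a 12-column
tab-delimited hit table (query id, subject feature id, percent identity,
alignment length, mismatches, gap opens, query start/end, subject
start/end, e-value, bit score).  Each query is credited to its best hit
(highest bit score; ties to the lexicographically first subject), and the
per-feature read counts are length-normalized into a profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MismatchError
from .model import TrainedModule, train_classifier
from .optimize import shrink_markers
from .profiles import (
    DATA_TYPE_FOR_RANK,
    RANK_FOR_DATA_TYPE,
    CountTable,
    FeatureAbundanceMatrix,
    SampleManifest,
    exclude_relative_health,
    normalize_counts,
)
from .selection import SelectionConfig, select_features
from .model import stage_cohort

logger = logging.getLogger(__name__)


@dataclass
class StagePair:
    """The two fitted stage modules sharing one data type."""

    stage1: TrainedModule  # health_vs_ibd, positive class IBD
    stage2: TrainedModule  # uc_vs_cd, positive class CD

    def __post_init__(self) -> None:
        if self.stage1.data_type != self.stage2.data_type:
            raise ValueError("stage modules must share a data type")
        if self.stage1.positive_class != "IBD" or self.stage2.positive_class != "CD":
            raise ValueError("stage1 must score IBD and stage2 must score CD")

    @property
    def data_type(self) -> str:
        return self.stage1.data_type

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.stage1.save(directory / "stage1")
        self.stage2.save(directory / "stage2")
        with open(directory / "bundle.json", "w") as fh:
            json.dump({"format_version": 1, "data_type": self.data_type}, fh)

    @classmethod
    def load(cls, directory) -> "StagePair":
        directory = Path(directory)
        return cls(
            TrainedModule.load(directory / "stage1"),
            TrainedModule.load(directory / "stage2"),
        )


def _align_profile(X: pd.DataFrame, feature_ids: Sequence[str]) -> pd.DataFrame:
    missing = [f for f in feature_ids if f not in X.columns]
    if missing:
        logger.warning(
            "query profile lacks %d model features (imputed as 0): %s",
            len(missing), missing[:10],
        )
    return X.reindex(columns=list(feature_ids), fill_value=0.0)


def predict_two_stage(
    fam: FeatureAbundanceMatrix, modules: StagePair
) -> pd.DataFrame:
    """Route every sample through the cascade; one call per sample.

    Returns a frame indexed by sample_id with columns ``call`` (Health, UC
    or CD), ``stage1_score`` and ``stage2_score`` (NaN unless stage 1
    called IBD).  Threshold equality calls the positive class, so the
    printed prevalence cutoffs behave as inclusive bounds.
    """
    if fam.data_type != modules.data_type:
        raise MismatchError(
            f"profile is {fam.data_type} ({fam.rank} rank) but the model "
            f"bundle expects {modules.data_type} data"
        )
    X1 = _align_profile(fam.data, modules.stage1.feature_ids)
    s1 = modules.stage1.scores(X1)
    is_ibd = s1 >= modules.stage1.threshold

    calls = np.where(is_ibd, "", "Health").astype(object)
    s2 = np.full(len(fam.data), np.nan)
    if is_ibd.any():
        ibd_rows = fam.data.index[is_ibd]
        X2 = _align_profile(fam.data.loc[ibd_rows], modules.stage2.feature_ids)
        scores2 = modules.stage2.scores(X2)
        s2[is_ibd] = scores2
        calls[is_ibd] = np.where(
            scores2 >= modules.stage2.threshold, "CD", "UC"
        )
    result = pd.DataFrame(
        {"call": calls, "stage1_score": s1, "stage2_score": s2},
        index=pd.Index(fam.sample_ids, name="sample_id"),
    )
    assert set(result["call"]) <= {"Health", "UC", "CD"}
    return result


def write_diagnosis(diagnosis: pd.DataFrame, path) -> None:
    """Diagnosis TSV with full-precision scores (byte-stable across runs)."""
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tcall\tstage1_score\tstage2_score\n")
        for sid, row in diagnosis.iterrows():
            s2 = "" if pd.isna(row.stage2_score) else repr(float(row.stage2_score))
            fh.write(f"{sid}\t{row.call}\t{float(row.stage1_score)!r}\t{s2}\n")


# ---------------------------------------------------------------------------
# Alignment hit tables -> counts
# ---------------------------------------------------------------------------

HIT_COLUMNS = 12


def counts_from_hits(
    path, feature_lengths: pd.Series, sample_id: str = "sample",
    rank: str = "strain",
) -> CountTable:
    """Reduce a 12-column tabular alignment file to best-hit read counts."""
    best: dict[str, tuple[float, str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != HIT_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {HIT_COLUMNS} "
                    f"tab-delimited fields, got {len(parts)}"
                )
            query, subject = parts[0], parts[1]
            try:
                bitscore = float(parts[11])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric bit score {parts[11]!r}"
                ) from None
            n_rows += 1
            prev = best.get(query)
            # best hit: higher bit score wins; ties to the lexicographically
            # first subject id
            if (
                prev is None
                or bitscore > prev[0]
                or (bitscore == prev[0] and subject < prev[1])
            ):
                best[query] = (bitscore, subject)
    if n_rows == 0:
        raise FormatError(f"{path}: no alignment rows (all-zero sample)")
    counts: dict[str, int] = {}
    for _, (_, subject) in best.items():
        counts[subject] = counts.get(subject, 0) + 1
    frame = pd.DataFrame(
        [counts], index=pd.Index([sample_id], name="sample_id")
    ).reindex(columns=sorted(counts), fill_value=0)
    return CountTable(frame, feature_lengths, rank=rank)


def profile_from_hits(
    path, feature_lengths: pd.Series, sample_id: str = "sample",
    data_type: str = "wgs",
) -> FeatureAbundanceMatrix:
    table = counts_from_hits(
        path, feature_lengths, sample_id, rank=RANK_FOR_DATA_TYPE[data_type]
    )
    return normalize_counts(table)


# ---------------------------------------------------------------------------
# Fitting both stages
# ---------------------------------------------------------------------------

def _fit_stage(
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    contrast: str,
    selection_cfg: SelectionConfig | None,
    backend: str,
    params: Mapping | None,
    seed: int,
    optimize: bool,
    curve_rounds: int,
) -> TrainedModule:
    sub_fam, sub_manifest, task, positive = stage_cohort(fam, manifest, contrast)
    result = select_features(sub_fam.data, task.values, selection_cfg)
    features = result.hubs
    if not features:
        logger.warning(
            "%s: selection returned no hubs; falling back to the "
            "abundance-filtered feature set", contrast,
        )
        features = result.after_abundance
    if not features:
        raise ValueError(f"{contrast}: no usable features after selection")
    if optimize and len(features) > 1:
        _, _, features = shrink_markers(
            fam, manifest, contrast=contrast, features=features,
            backend=backend, params=params, seed=seed, rounds=curve_rounds,
        )
    module = train_classifier(
        sub_fam.data[features], task.values, positive, stage=contrast,
        data_type=sub_fam.data_type, backend=backend, params=params, seed=seed,
    )
    logger.info(
        "%s: trained %s on %d features, threshold %.2f (unrounded %r)",
        contrast, backend, len(features), round(module.threshold, 2),
        module.threshold,
    )
    return module


def fit_two_stage(
    fam: FeatureAbundanceMatrix,
    manifest: SampleManifest,
    selection_cfg: SelectionConfig | None = None,
    backend: str = "lightgbm",
    params: Mapping | None = None,
    seed: int = 0,
    optimize: bool = False,
    curve_rounds: int = 3,
) -> StagePair:
    """Fit the Health-vs-IBD and UC-vs-CD modules on one training cohort.

    RelativeHealth samples are excluded up front; ``optimize=True`` runs
    marker-set shrinkage per stage before the final fit.
    """
    manifest = exclude_relative_health(manifest)
    fam = fam.subset_samples(manifest.sample_ids)
    stage1 = _fit_stage(
        fam, manifest, "health_vs_ibd", selection_cfg, backend, params, seed,
        optimize, curve_rounds,
    )
    stage2 = _fit_stage(
        fam, manifest, "uc_vs_cd", selection_cfg, backend, params, seed,
        optimize, curve_rounds,
    )
    return StagePair(stage1, stage2)
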