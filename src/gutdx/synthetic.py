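"""Synthetic gut-microbiome cohorts with known ground truth.

Compositions are logistic-normal: each individual draws a latent
log-abundance vector (feature baselines + correlated block factors +
individual noise), each of their samples adds fresh sample-level noise,
and rows are closed to sum 1.  This reproduces the properties the
pipeline's statistics rely on — compositional closure, heavy-tailed
abundances, within-block Spearman correlation, and resequenced samples
that resemble each other far more than samples from other individuals
(the leakage hazard grouped cross-validation exists to prevent).

Planted case/control effects shift the chosen features' latent
log-abundance in the case class (IBD for the first contrast, CD for the
second), and the planted ids are returned as ground truth.  Note that
closure couples features: boosting the planted features in cases deflates
every other feature's relative abundance there, which is genuine
compositional behaviour, not an artifact.

The "paper-shape" preset reproduces the study cohort arithmetic: 318
individuals, 78 of the non-relative-health ones sequenced twice, 47
single-sample relative-health individuals, giving 396 samples of which
349 (201 Health, 127 UC, 21 CD) remain after exclusion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    LABELS,
    FeatureAbundanceMatrix,
    SampleManifest,
    SampleRecord,
    write_fam,
    write_manifest,
)

logger = logging.getLogger(__name__)

CONTRAST_CASE = {"health_vs_ibd": ("UC", "CD"), "uc_vs_cd": ("CD",)}


@dataclass(frozen=True)
class CorrelationBlock:
    """A group of features sharing a latent factor with target |rho|."""

    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        if not (0 < self.rho < 1):
            raise ValueError("target |rho| must lie in (0, 1)")


@dataclass
class CohortSpec:
    """Study-design knobs for one simulated cohort."""

    n_individuals: int = 318
    #: fraction of non-RelativeHealth individuals sequenced twice
    fraction_resequenced: float = 78 / 271
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "Health": 156 / 318, "UC": 99 / 318, "CD": 16 / 318,
            "RelativeHealth": 47 / 318,
        }
    )
    n_features: int = 150
    #: planted differential features per contrast
    n_differential: dict[str, int] = field(
        default_factory=lambda: {"health_vs_ibd": 8, "uc_vs_cd": 5}
    )
    log_effect_size: float = 1.5
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    #: sd of sample-level log-abundance noise (within-individual)
    noise_dispersion: float = 0.3
    seed: int = 0
    #: sd of between-individual latent variation
    individual_sigma: float = 1.0
    #: sd of feature baseline log-abundances (heavy-tailed compositions)
    base_sigma: float = 1.5
    data_type: str = "wgs"
    #: optional exact per-class individual counts (overrides proportions)
    class_individuals: dict[str, int] | None = None
    #: optional exact per-class resequencing counts (overrides the fraction)
    resequenced_per_class: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not (0 <= self.fraction_resequenced <= 1):
            raise ValueError("fraction_resequenced must lie in [0, 1]")
        for label in self.class_proportions:
            if label not in LABELS:
                raise ValueError(f"unknown class {label!r}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        self.correlation_blocks = [
            b if isinstance(b, CorrelationBlock) else CorrelationBlock(*b)
            for b in self.correlation_blocks
        ]
        n_planted = sum(self.n_differential.values())
        if n_planted > self.n_features:
            raise ValueError("more differential features than features")
        n_block = sum(b.size for b in self.correlation_blocks)
        if n_planted + n_block > self.n_features:
            raise ValueError(
                "correlation blocks and planted features exceed n_features"
            )


@dataclass
class CohortBundle:
    """Simulated FAM + manifest + planted ground truth."""

    fam: FeatureAbundanceMatrix
    manifest: SampleManifest
    truth: dict
    spec: CohortSpec

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fam(self.fam, directory / "fam.tsv")
        write_manifest(self.manifest, directory / "manifest.tsv")
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _largest_remainder(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``total`` across keys so counts match proportions exactly."""
    keys = list(proportions)
    quotas = np.array([proportions[k] * total for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return dict(zip(keys, counts.tolist()))


def simulate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a cohort fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    if spec.class_individuals is not None:
        class_counts = dict(spec.class_individuals)
        if sum(class_counts.values()) != spec.n_individuals:
            raise ValueError("class_individuals must sum to n_individuals")
    else:
        class_counts = _largest_remainder(spec.n_individuals, spec.class_proportions)

    non_rh = {c: n for c, n in class_counts.items() if c != "RelativeHealth"}
    if spec.resequenced_per_class is not None:
        reseq_counts = dict(spec.resequenced_per_class)
    else:
        n_reseq = int(round(spec.fraction_resequenced * sum(non_rh.values())))
        if sum(non_rh.values()) > 0 and n_reseq > 0:
            reseq_counts = _largest_remainder(
                n_reseq, {c: n / sum(non_rh.values()) for c, n in non_rh.items()}
            )
        else:
            reseq_counts = {c: 0 for c in non_rh}
    for cls, n in reseq_counts.items():
        if n > non_rh.get(cls, 0):
            raise ValueError(f"cannot resequence {n} of {non_rh.get(cls, 0)} {cls!r}")

    # individuals grouped by class, ids sequential; RelativeHealth single-sample
    individuals: list[tuple[str, str, bool]] = []  # (id, label, resequenced)
    idx = 0
    for label in [lab for lab in LABELS if class_counts.get(lab, 0) > 0]:
        n_cls = class_counts[label]
        n_reseq_cls = reseq_counts.get(label, 0) if label != "RelativeHealth" else 0
        for i in range(n_cls):
            idx += 1
            individuals.append((f"I{idx:04d}", label, i < n_reseq_cls))

    features = [f"F{i + 1:04d}" for i in range(spec.n_features)]
    # planted differential features first, then block members, then free noise
    truth_diff: dict[str, list[str]] = {}
    cursor = 0
    effects = np.zeros((len(LABELS), spec.n_features))
    label_index = {l: i for i, l in enumerate(LABELS)}
    for contrast in ("health_vs_ibd", "uc_vs_cd"):
        d = spec.n_differential.get(contrast, 0)
        planted = features[cursor:cursor + d]
        truth_diff[contrast] = planted
        for case_label in CONTRAST_CASE[contrast]:
            effects[label_index[case_label], cursor:cursor + d] += spec.log_effect_size
        cursor += d
    blocks: list[list[str]] = []
    block_of = np.full(spec.n_features, -1)
    for b_idx, block in enumerate(spec.correlation_blocks):
        members = features[cursor:cursor + block.size]
        blocks.append(members)
        block_of[cursor:cursor + block.size] = b_idx
        cursor += block.size

    mu = rng.normal(0.0, spec.base_sigma, spec.n_features)
    n_ind = len(individuals)
    z = rng.standard_normal((n_ind, spec.n_features))
    if spec.correlation_blocks:
        u = rng.standard_normal((n_ind, len(spec.correlation_blocks)))
        for b_idx, block in enumerate(spec.correlation_blocks):
            # latent Pearson c chosen so the induced Spearman matches the
            # target: Spearman(rho) = (6/pi) asin(c/2) for bivariate normals
            c = min(2.0 * math.sin(math.pi * block.rho / 6.0), 0.999)
            cols = block_of == b_idx
            z[:, cols] = (
                math.sqrt(c) * u[:, [b_idx]]
                + math.sqrt(1.0 - c) * z[:, cols]
            )

    latent = np.empty((n_ind, spec.n_features))
    for i, (_, label, _) in enumerate(individuals):
        latent[i] = mu + spec.individual_sigma * z[i] + effects[label_index[label]]

    records: list[SampleRecord] = []
    sample_rows: list[int] = []
    sid = 0
    for i, (ind_id, label, reseq) in enumerate(individuals):
        for _ in range(2 if reseq else 1):
            sid += 1
            records.append(
                SampleRecord(f"S{sid:04d}", ind_id, label, spec.data_type)
            )
            sample_rows.append(i)
    n_samples = len(records)
    noise = rng.standard_normal((n_samples, spec.n_features))
    log_x = latent[sample_rows] + spec.noise_dispersion * noise
    x = np.exp(log_x)
    x /= x.sum(axis=1, keepdims=True)

    fam = FeatureAbundanceMatrix(
        pd.DataFrame(x, index=[r.sample_id for r in records], columns=features),
        rank="strain" if spec.data_type == "wgs" else "genus",
    )
    manifest = SampleManifest(records)
    truth = {
        "differential": truth_diff,
        "blocks": blocks,
        "n_samples": n_samples,
        "seed": spec.seed,
    }
    return CohortBundle(fam, manifest, truth, spec)


# ---------------------------------------------------------------------------
# Seed-pinned fixture presets used across the test suite
# ---------------------------------------------------------------------------

def _paper_shape_spec() -> CohortSpec:
    return CohortSpec(
        n_individuals=318,
        fraction_resequenced=78 / 271,
        class_proportions={
            "Health": 156 / 318, "UC": 99 / 318, "CD": 16 / 318,
            "RelativeHealth": 47 / 318,
        },
        class_individuals={"Health": 156, "UC": 99, "CD": 16, "RelativeHealth": 47},
        resequenced_per_class={"Health": 45, "UC": 28, "CD": 5},
        n_features=150,
        n_differential={"health_vs_ibd": 8, "uc_vs_cd": 5},
        log_effect_size=1.5,
        correlation_blocks=[CorrelationBlock(5, 0.8), CorrelationBlock(4, 0.6)],
        noise_dispersion=0.3,
        seed=7,
    )


def _tiny_separable_spec() -> CohortSpec:
    # 36 individuals, 4 resequenced -> 40 samples.  Constructed to be
    # separable whichever single representative the redundancy collapse
    # keeps: even baseline shares (base_sigma 1) and low within-group
    # variation make both the boosted markers and the closure-deflated
    # background separate the groups by several standard deviations.
    return CohortSpec(
        n_individuals=36,
        fraction_resequenced=4 / 36,
        class_proportions={"Health": 0.5, "UC": 0.5},
        class_individuals={"Health": 18, "UC": 18},
        resequenced_per_class={"Health": 2, "UC": 2},
        n_features=20,
        n_differential={"health_vs_ibd": 5, "uc_vs_cd": 0},
        log_effect_size=3.0,
        correlation_blocks=[],
        noise_dispersion=0.1,
        seed=3,
        individual_sigma=0.15,
        base_sigma=0.5,
    )


def _tiny_null_spec() -> CohortSpec:
    # labels carry no signal; sized so a 5-fold mean AUC concentrates near 0.5
    return CohortSpec(
        n_individuals=100,
        fraction_resequenced=0.2,
        class_proportions={"Health": 0.5, "UC": 0.5},
        n_features=20,
        n_differential={"health_vs_ibd": 0, "uc_vs_cd": 0},
        log_effect_size=0.0,
        correlation_blocks=[],
        noise_dispersion=0.3,
        seed=5,
    )


def _planted_markers_spec() -> CohortSpec:
    # marker-recovery benchmark: 5 informative / 45 noise features.  The
    # effect (1.5 log units, ~4.5x fold change) is strong for rank-sum
    # detection yet keeps pooled between-marker |rho| below the strong-edge
    # cutoff, so redundancy collapse does not merge the planted markers;
    # 300 individuals give the survivor network enough nodes to iterate.
    return CohortSpec(
        n_individuals=300,
        fraction_resequenced=0.2,
        class_proportions={"Health": 0.5, "UC": 0.5},
        n_features=50,
        n_differential={"health_vs_ibd": 5, "uc_vs_cd": 0},
        log_effect_size=1.5,
        correlation_blocks=[],
        noise_dispersion=0.3,
        seed=11,
    )


def _tiny_cohort_spec() -> CohortSpec:
    # three classes for two-stage end-to-end runs
    return CohortSpec(
        n_individuals=40,
        fraction_resequenced=0.15,
        class_proportions={"Health": 0.4, "UC": 0.4, "CD": 0.2},
        class_individuals={"Health": 16, "UC": 16, "CD": 8},
        n_features=30,
        n_differential={"health_vs_ibd": 5, "uc_vs_cd": 4},
        log_effect_size=3.5,
        correlation_blocks=[CorrelationBlock(4, 0.8)],
        noise_dispersion=0.3,
        seed=13,
    )


FIXTURES = {
    "paper-shape": _paper_shape_spec,
    "tiny-separable": _tiny_separable_spec,
    "tiny-null": _tiny_null_spec,
    "planted-markers": _planted_markers_spec,
    "tiny-cohort": _tiny_cohort_spec,
}


def make_fixture(name: str) -> CohortBundle:
    """Build a registered, seed-pinned cohort preset."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        ) from None
    return simulate_cohort(factory())
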