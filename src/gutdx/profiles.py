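"""Feature-abundance profiles, sample manifests and their TSV formats.

The universal currency of the pipeline is the feature abundance matrix
(FAM): a samples x features table of relative abundances, each row closed
to sum 1.  WGS mode works at strain rank, 16S mode at genus rank; genus
profiles are obtained by summing the member-strain abundances.

Raw aligned-read counts are turned into relative abundances by dividing
each count by its feature's reference length (length correction) and then
closing each sample to unit sum (depth correction).  The two corrections
commute under closure, so the order is immaterial.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

LABELS = ("Health", "UC", "CD", "RelativeHealth")
IBD_LABELS = ("UC", "CD")
RANKS = ("strain", "genus")
DATA_TYPES = ("wgs", "16s")
#: taxonomic rank of the features each data type profiles
RANK_FOR_DATA_TYPE = {"wgs": "strain", "16s": "genus"}
DATA_TYPE_FOR_RANK = {"strain": "wgs", "genus": "16s"}

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced stool sample and its bookkeeping."""

    sample_id: str
    individual_id: str
    label: str
    data_type: str = "wgs"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r} for sample {self.sample_id!r}; "
                f"expected one of {LABELS}"
            )
        if self.data_type not in DATA_TYPES:
            raise ValueError(
                f"unknown data_type {self.data_type!r} for sample "
                f"{self.sample_id!r}; expected one of {DATA_TYPES}"
            )


@dataclass
class SampleManifest:
    """Ordered collection of samples; individuals may repeat (resequencing)."""

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r} in manifest")
            seen.add(rec.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def individuals(self) -> list[str]:
        """Unique individual ids in first-appearance order."""
        return list(dict.fromkeys(r.individual_id for r in self.records))

    def labels(self) -> pd.Series:
        """Sample label per sample_id."""
        return pd.Series(
            {r.sample_id: r.label for r in self.records}, name="label"
        ).reindex(self.sample_ids)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def individual_labels(self) -> dict[str, str]:
        """Label per individual; raises if an individual's samples disagree."""
        labels: dict[str, str] = {}
        for r in self.records:
            prev = labels.get(r.individual_id)
            if prev is not None and prev != r.label:
                raise ValueError(
                    f"individual {r.individual_id!r} has conflicting labels "
                    f"{prev!r} and {r.label!r}"
                )
            labels[r.individual_id] = r.label
        return labels

    def subset(self, sample_ids: Iterable[str]) -> "SampleManifest":
        wanted = set(sample_ids)
        return SampleManifest([r for r in self.records if r.sample_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.individual_id, r.label, r.data_type) for r in self.records],
            columns=["sample_id", "individual_id", "label", "data_type"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleManifest":
        records = [
            SampleRecord(
                str(row.sample_id), str(row.individual_id), str(row.label),
                str(row.data_type),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records)


@dataclass
class CountTable:
    """Raw aligned-read counts (samples x features) plus reference lengths."""

    counts: pd.DataFrame
    feature_length: pd.Series
    rank: str = "strain"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class FeatureAbundanceMatrix:
    """Relative abundances (samples x features), each row summing to 1."""

    data: pd.DataFrame
    rank: str = "strain"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids in abundance matrix")
        values = self.data.values
        if not np.isfinite(values).all():
            raise ValueError("abundances must be finite")
        if (values < 0).any() or (values > 1).any():
            raise ValueError("abundances must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        bad = np.abs(row_sums - 1.0) > ROW_SUM_TOL
        if bad.any():
            offenders = list(self.data.index[bad][:5])
            raise ValueError(
                f"abundance rows must sum to 1 within {ROW_SUM_TOL}; offenders "
                f"include {offenders}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def data_type(self) -> str:
        return DATA_TYPE_FOR_RANK[self.rank]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureAbundanceMatrix":
        return replace(self, data=self.data.loc[list(sample_ids)])


def normalize_counts(table: CountTable) -> FeatureAbundanceMatrix:
    """Length-correct read counts and close each sample to relative abundances.

    abundance(f, s) = (count(f, s) / length(f)) / sum_g (count(g, s) / length(g))
    """
    lengths = table.feature_length.reindex(table.counts.columns)
    missing = lengths.index[lengths.isna()]
    if len(missing):
        raise ValueError(f"missing feature lengths for {list(missing[:5])}")
    if (lengths <= 0).any():
        offenders = list(lengths.index[lengths <= 0][:5])
        raise ValueError(f"feature lengths must be positive; offenders {offenders}")
    rates = table.counts.astype(float).div(lengths.astype(float), axis=1)
    totals = rates.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        offenders = list(totals.index[zero][:5])
        raise ValueError(
            f"samples with no aligned reads cannot be normalized: {offenders}"
        )
    abundances = rates.div(totals, axis=0)
    return FeatureAbundanceMatrix(abundances, rank=table.rank)


def aggregate_to_genus(
    fam: FeatureAbundanceMatrix, taxonomy: Mapping[str, str]
) -> FeatureAbundanceMatrix:
    """Sum member-strain abundances into genus abundances (mass-conserving)."""
    if fam.rank != "strain":
        raise ValueError(f"can only aggregate strain-rank profiles, got {fam.rank!r}")
    unmapped = [f for f in fam.feature_ids if f not in taxonomy]
    if unmapped:
        raise ValueError(f"strains missing from taxonomy map: {unmapped[:10]}")
    genera = [taxonomy[f] for f in fam.feature_ids]
    # keep genera in first-appearance order of their member strains
    order = list(dict.fromkeys(genera))
    grouped = fam.data.T.groupby(pd.Index(genera, name="genus"), sort=False).sum().T
    grouped = grouped[order]
    return FeatureAbundanceMatrix(grouped, rank="genus")


def exclude_relative_health(manifest: SampleManifest) -> SampleManifest:
    """Drop samples whose disease status is uncertain (RelativeHealth)."""
    kept = [r for r in manifest.records if r.label != "RelativeHealth"]
    return SampleManifest(kept)


# ---------------------------------------------------------------------------
# TSV serialization.  Layout: rows = samples, columns = features, first
# column sample_id.  Floats are written with repr (shortest round-trip), so
# write -> read is the identity on values.
# ---------------------------------------------------------------------------

def write_fam(fam: FeatureAbundanceMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", *fam.feature_ids])
        for sid, row in zip(fam.sample_ids, fam.data.values):
            writer.writerow([sid, *[repr(float(v)) for v in row]])


def _read_table(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip() != ""]
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
    return rows


def read_fam(path, rank: str = "strain") -> FeatureAbundanceMatrix:
    rows = _read_table(path)
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: header must list at least one feature")
    features = header[1:]
    if len(set(features)) != len(features):
        raise FormatError(f"{path}: duplicate feature ids in header")
    sample_ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        sid = row[0]
        if sid in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        parsed = []
        for col, cell in zip(features, row[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} "
                    f"in column {col!r}"
                ) from None
        sample_ids.append(sid)
        values.append(parsed)
    if not sample_ids:
        raise FormatError(f"{path}: no sample rows")
    data = pd.DataFrame(values, index=sample_ids, columns=features)
    return FeatureAbundanceMatrix(data, rank=rank)


MANIFEST_COLUMNS = ("sample_id", "individual_id", "label", "data_type")


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SampleManifest:
    rows = _read_table(path)
    header = tuple(rows[0])
    if header != MANIFEST_COLUMNS:
        raise FormatError(
            f"{path}: manifest header must be {list(MANIFEST_COLUMNS)}, got {list(header)}"
        )
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            records.append(SampleRecord(*row))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    try:
        return SampleManifest(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_taxonomy(taxonomy: Mapping[str, str], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("strain_id\tgenus_id\n")
        for strain, genus in taxonomy.items():
            fh.write(f"{strain}\t{genus}\n")


def read_taxonomy(path) -> dict[str, str]:
    rows = _read_table(path)
    if tuple(rows[0]) != ("strain_id", "genus_id"):
        raise FormatError(f"{path}: taxonomy header must be ['strain_id', 'genus_id']")
    taxonomy: dict[str, str] = {}
    for lineno, (strain, genus) in enumerate(rows[1:], start=2):
        if strain in taxonomy:
            raise FormatError(f"{path}: line {lineno}: duplicate strain_id {strain!r}")
        taxonomy[strain] = genus
    return taxonomy


def read_feature_lengths(path) -> pd.Series:
    rows = _read_table(path)
    if tuple(rows[0]) != ("feature_id", "length"):
        raise FormatError(f"{path}: lengths header must be ['feature_id', 'length']")
    ids, lengths = [], []
    for lineno, (fid, length) in enumerate(rows[1:], start=2):
        if fid in ids:
            raise FormatError(f"{path}: line {lineno}: duplicate feature_id {fid!r}")
        try:
            value = int(length)
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-integer length {length!r}"
            ) from None
        ids.append(fid)
        lengths.append(value)
    return pd.Series(lengths, index=ids, name="length")
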