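"""Core domain types and TSV readers/writers.

The canonical exchange format for every table is tab-separated UTF-8 text
with a header row.  Feature (count) tables default to phylotypes-as-rows,
matching the common amplicon feature-table convention; a flag transposes.

The internal standard — a defined number of cells of a taxon absent from
the studied environment, spiked into each sample before filtration — is
identified everywhere by an explicit phylotype id, never by matching
taxonomy strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "CellCountSeries",
    "ValidatedDataset",
    "DataError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "read_taxonomy",
    "read_cell_counts",
    "validate_dataset",
]

#: default treatment labels: unmanipulated control, 1.2-um filtered
#: (grazer-removed), and filtered + phosphate-amended
DEFAULT_TREATMENTS = ("C", "F", "FP")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class CountTable:
    """Reads per phylotype per sample, including the internal-standard row.

    ``counts`` is a phylotype × sample DataFrame.  Entries are non-negative;
    tables read from disk are integers, while expectation-mode simulator
    output may carry fractional expected reads.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] == 0:
            raise DataError("no samples in count table")
        if df.shape[0] == 0:
            return  # empty phylotype set: legal (e.g. an over-aggressive filter)
        dup_p = df.index[df.index.duplicated()].unique().tolist()
        if dup_p:
            raise DataError(f"duplicate phylotype id(s): {dup_p}")
        dup_s = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_s:
            raise DataError(f"duplicate sample id(s): {dup_s}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("count table contains non-numeric entries")
        if np.isnan(values).any():
            raise DataError("count table contains missing values")
        if (values < 0).any():
            raise DataError("count table contains negative entries")
        empty = df.columns[(values.sum(axis=0) == 0)].tolist()
        if empty:
            raise DataError(f"sample(s) with all-zero counts: {empty}")

    @property
    def phylotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def drop(self, phylotype_ids: Iterable[str]) -> "CountTable":
        return CountTable(self.counts.drop(index=list(phylotype_ids)))

    def total_reads(self) -> float:
        return float(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class SampleMetadata:
    """One sequenced sample: treatment bottle × time point × replicate."""

    sample_id: str
    treatment: str
    time_h: float
    replicate: str
    sample_volume_ml: float | None = None
    spike_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise DataError(
                f"sample {self.sample_id!r}: negative time_h {self.time_h}"
            )
        if self.sample_volume_ml is not None and self.sample_volume_ml <= 0:
            raise DataError(f"sample {self.sample_id!r}: non-positive volume")
        if self.spike_volume_ul is not None and self.spike_volume_ul < 0:
            raise DataError(f"sample {self.sample_id!r}: negative spike volume")


@dataclass
class TaxonomyTable:
    """Ranked lineage per phylotype plus the designated internal-standard id."""

    lineages: pd.DataFrame  # index: phylotype_id; columns: rank names
    standard_id: str

    def __post_init__(self) -> None:
        if self.standard_id not in self.lineages.index:
            raise DataError(
                f"internal standard {self.standard_id!r} absent from taxonomy"
            )
        if self.lineages.index.duplicated().any():
            dups = self.lineages.index[self.lineages.index.duplicated()].tolist()
            raise DataError(f"duplicate phylotype id(s) in taxonomy: {dups}")

    @property
    def ranks(self) -> list[str]:
        return list(self.lineages.columns)

    def label(self, phylotype_id: str, rank: str) -> str:
        if rank not in self.lineages.columns:
            raise DataError(f"rank {rank!r} not in taxonomy ranks {self.ranks}")
        return str(self.lineages.loc[phylotype_id, rank])


@dataclass
class CellCountSeries:
    """Absolute cell abundances (microscopy / flow cytometry) over time."""

    data: pd.DataFrame  # columns: group, treatment, time_h, replicate, cells_per_ml

    REQUIRED = ("group", "treatment", "time_h", "replicate", "cells_per_ml")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DataError(f"cell-count series missing column(s): {missing}")
        if (self.data["cells_per_ml"] <= 0).any():
            raise DataError("cell-count series must be strictly positive")


@dataclass
class ValidatedDataset:
    """Counts, metadata and taxonomy aligned on a common sample set."""

    counts: CountTable
    metadata: list[SampleMetadata]
    taxonomy: TaxonomyTable

    @property
    def standard_id(self) -> str:
        return self.taxonomy.standard_id

    def metadata_frame(self) -> pd.DataFrame:
        return metadata_frame(self.metadata)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, samples_as_rows: bool = False) -> CountTable:
    """Read a TSV feature table (first column = phylotype ids by default)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: no phylotypes")
    if samples_as_rows:
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataError(f"{path}: non-numeric counts")
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise DataError(f"{path}: non-integer counts")
    if (values < 0).any():
        raise DataError(f"{path}: negative counts")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="phylotype_id")


_META_REQUIRED = ("sample_id", "treatment", "time_h", "replicate")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata; validates the design-triple uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                treatment=str(row.treatment),
                time_h=float(row.time_h),
                replicate=str(row.replicate),
                sample_volume_ml=(
                    float(row.sample_volume_ml)
                    if "sample_volume_ml" in df.columns
                    and not pd.isna(row.sample_volume_ml)
                    else None
                ),
                spike_volume_ul=(
                    float(row.spike_volume_ul)
                    if "spike_volume_ul" in df.columns
                    and not pd.isna(row.spike_volume_ul)
                    else None
                ),
            )
        )
    _check_unique_design(records)
    return records


def _check_unique_design(records: Sequence[SampleMetadata]) -> None:
    seen: dict[tuple, str] = {}
    for rec in records:
        triple = (rec.treatment, rec.time_h, rec.replicate)
        if triple in seen:
            raise DataError(
                f"duplicate (treatment, time_h, replicate) triple {triple} "
                f"in samples {seen[triple]!r} and {rec.sample_id!r}"
            )
        seen[triple] = rec.sample_id
    ids = [r.sample_id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise DataError(f"duplicate sample id(s) in metadata: {sorted(dup)}")


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tidy DataFrame view of metadata records, indexed by sample id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "treatment": [r.treatment for r in records],
            "time_h": [r.time_h for r in records],
            "replicate": [r.replicate for r in records],
        }
    )
    return df.set_index("sample_id")


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path, standard_id: str) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df, standard_id=str(standard_id))


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.lineages.to_csv(path, sep="\t", index_label="phylotype_id")


def read_cell_counts(path: str | Path) -> CellCountSeries:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "treatment": str})
    return CellCountSeries(df)


# ---------------------------------------------------------------------------
# dataset validation


def validate_dataset(
    counts: CountTable,
    metadata: Sequence[SampleMetadata],
    taxonomy: TaxonomyTable,
) -> ValidatedDataset:
    """Align counts with metadata and check the internal standard.

    The spike-in standard must be present with nonzero reads in every
    sample: a zero standard makes the normalization ratio undefined.
    Order-insensitive in samples and idempotent.
    """
    _check_unique_design(metadata)
    count_samples = set(counts.sample_ids)
    meta_samples = {r.sample_id for r in metadata}
    only_counts = sorted(count_samples - meta_samples)
    if only_counts:
        raise DataError(f"sample(s) in counts but not metadata: {only_counts}")
    only_meta = sorted(meta_samples - count_samples)
    if only_meta:
        raise DataError(f"sample(s) in metadata but not counts: {only_meta}")

    std = taxonomy.standard_id
    if std not in counts.counts.index:
        raise DataError(f"internal standard {std!r} absent from count table")
    std_row = counts.counts.loc[std]
    zero = sorted(std_row.index[std_row == 0].tolist())
    if zero:
        raise DataError(
            f"internal standard {std!r} has zero reads in sample(s): {zero}"
        )

    # canonical ordering: metadata order defines the sample order
    order = [r.sample_id for r in metadata]
    aligned = CountTable(counts.counts.loc[:, order])
    return ValidatedDataset(aligned, list(metadata), taxonomy)
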