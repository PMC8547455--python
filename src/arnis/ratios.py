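"""Prevalence filtering, spike-in normalization ratios, and growth curves.

Amplicon read counts are compositional: PCR bias and varying library depth
make raw reads incomparable across samples.  Dividing each phylotype's
reads by the reads of a spiked-in internal standard (a fixed number of
cells per unit volume of sample) cancels the per-sample depth factor, so
the ratio tracks the phylotype's absolute abundance up to a constant,
phylotype-specific PCR-bias factor.  Constant factors drop out of
log-slope growth-rate estimates downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, SampleMetadata, ValidatedDataset, metadata_frame

__all__ = [
    "FilterResult",
    "ArnisTable",
    "GrowthCurveSet",
    "filter_phylotypes",
    "compute_arnis",
    "build_growth_curves",
    "FILTER_PRESETS",
]

#: prevalence-filter presets: (min_count, min_sample_fraction).
#: "16S" is the whole-community preset, "pufM" the functional-gene preset
#: for aerobic anoxygenic phototrophs, whose libraries are sparser.
FILTER_PRESETS: dict[str, tuple[int, float]] = {
    "16S": (10, 0.15),
    "pufM": (3, 0.15),
}


@dataclass
class FilterResult:
    """Filtered table plus what the filter removed."""

    counts: CountTable
    n_phylotypes_before: int
    n_phylotypes_after: int
    fraction_phylotypes_removed: float
    fraction_reads_removed: float


def filter_phylotypes(
    counts: CountTable,
    min_count: int = 10,
    min_sample_fraction: float = 0.15,
    protected_ids: Iterable[str] = (),
) -> FilterResult:
    """Keep a phylotype iff it has >= min_count reads in >= min_sample_fraction
    of all samples (treatments pooled).

    Rare, low-prevalence phylotypes carry most of the feature count but a
    tiny share of reads; removing them stabilizes every downstream per-
    phylotype statistic.  ``protected_ids`` (typically the internal
    standard) are kept unconditionally.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not 0 <= min_sample_fraction <= 1:
        raise ValueError("min_sample_fraction must be in [0, 1]")
    df = counts.counts
    n_samples = df.shape[1]
    prevalence = (df >= min_count).sum(axis=1) / n_samples
    keep = prevalence >= min_sample_fraction
    protected = df.index.isin(set(protected_ids))
    keep = keep | protected

    kept_df = df.loc[keep]
    n_before = df.shape[0]
    n_after = kept_df.shape[0]
    total = df.to_numpy().sum()
    removed_reads = total - kept_df.to_numpy().sum()
    if n_after - int(protected.sum()) == 0:
        warnings.warn(
            "prevalence filter removed every non-protected phylotype",
            stacklevel=2,
        )
    return FilterResult(
        counts=CountTable(kept_df),
        n_phylotypes_before=n_before,
        n_phylotypes_after=n_after,
        fraction_phylotypes_removed=(n_before - n_after) / n_before,
        fraction_reads_removed=float(removed_reads / total) if total else 0.0,
    )


@dataclass
class ArnisTable:
    """Per-sample ratio of phylotype reads to internal-standard reads.

    The standard row itself is excluded (its ratio is identically 1).
    """

    ratios: pd.DataFrame  # phylotype × sample, float
    standard_id: str

    def __post_init__(self) -> None:
        if self.standard_id in self.ratios.index:
            raise ValueError("standard must not appear as a ratio row")
        if (self.ratios.to_numpy() < 0).any():
            raise ValueError("ratios must be non-negative")

    @property
    def phylotype_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.columns)


def compute_arnis(validated: ValidatedDataset) -> ArnisTable:
    """ratio[p, s] = counts[p, s] / counts[standard, s].

    Validation guarantees the standard has nonzero reads everywhere, so the
    ratio is always defined.  Multiplying every count of a sample by a
    common factor (a depth change) leaves that sample's ratios unchanged.
    """
    std = validated.standard_id
    df = validated.counts.counts
    std_reads = df.loc[std].astype(float)
    ratios = df.drop(index=std).astype(float).div(std_reads, axis=1)
    return ArnisTable(ratios=ratios, standard_id=std)


@dataclass
class GrowthCurveSet:
    """Time-ordered per-replicate ratio series per phylotype × treatment.

    ``data`` is tidy: one row per (phylotype, treatment, time_h, replicate)
    observation.  Replicates missing at a time point are simply absent —
    never imputed.
    """

    data: pd.DataFrame  # columns: phylotype, treatment, time_h, replicate, ratio

    def phylotypes(self) -> list[str]:
        return sorted(self.data["phylotype"].unique())

    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    def replicate_series(
        self, phylotype: str, treatment: str, replicate: str
    ) -> pd.DataFrame:
        sel = self.data[
            (self.data["phylotype"] == phylotype)
            & (self.data["treatment"] == treatment)
            & (self.data["replicate"] == replicate)
        ]
        return sel.sort_values("time_h")[["time_h", "ratio"]].reset_index(drop=True)

    def mean_curve(self, phylotype: str, treatment: str) -> pd.DataFrame:
        """Replicate-mean ratio per time point (arithmetic mean of the
        replicates present at that time)."""
        sel = self.data[
            (self.data["phylotype"] == phylotype)
            & (self.data["treatment"] == treatment)
        ]
        out = (
            sel.groupby("time_h")["ratio"]
            .agg(mean_ratio="mean", n_replicates="count")
            .reset_index()
            .sort_values("time_h")
            .reset_index(drop=True)
        )
        return out


def build_growth_curves(
    arnis: ArnisTable, metadata: Sequence[SampleMetadata]
) -> GrowthCurveSet:
    """Assemble per-phylotype growth curves from the ratio table.

    Ratios are computed per sample first; replicate averaging happens only
    at curve level (`mean_curve`), never before.
    """
    meta = metadata_frame(metadata)
    missing = [s for s in arnis.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"sample(s) without metadata: {missing}")

    long = (
        arnis.ratios.rename_axis(index="phylotype", columns="sample_id")
        .stack()
        .rename("ratio")
        .reset_index()
    )
    long = long.merge(
        meta.reset_index()[["sample_id", "treatment", "time_h", "replicate"]],
        on="sample_id",
        how="left",
    )
    long = long[["phylotype", "treatment", "time_h", "replicate", "ratio"]]
    long = long.sort_values(
        ["phylotype", "treatment", "time_h", "replicate"]
    ).reset_index(drop=True)
    return GrowthCurveSet(long)
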