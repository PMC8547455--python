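"""Response classification: top-down vs bottom-up control of phylotypes.

A grazer-removal experiment with an optional phosphate amendment yields
two fold changes of growth rate per phylotype:

* F/C   — filtered (grazer-free) over control: response to relaxed
  top-down (predation) pressure;
* F+P/F — filtered + phosphate over filtered: response to relaxed
  bottom-up (phosphorus) limitation.

With a threshold T separating "weak" from "strong" responses, phylotypes
partition into group I (both strong: opportunists released by both
manipulations), group II (grazing-released only), group III
(phosphate-stimulated only), and NR (no response).  The default T = 1.3
corresponds to the 25th percentile of the pooled fold-change distribution
observed in the Adriatic coastal experiment this pipeline was built
around; it can be re-derived from any rate table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, SampleMetadata, TaxonomyTable, metadata_frame
from .growth import GrowthRateTable

__all__ = [
    "ResponseRecord",
    "ThresholdSpec",
    "GROUPS",
    "fold_changes",
    "derive_threshold",
    "classify_response",
    "classify_records",
    "aggregate_by_taxon",
    "relative_share",
    "DEFAULT_ROLES",
]

GROUPS = ("I", "II", "III", "NR", "NA")

#: treatment-role map: which label plays which part in the design
DEFAULT_ROLES: dict[str, str] = {
    "control": "C",
    "filtered": "F",
    "filtered_p": "FP",
}

_REQUIRED_ROLES = ("control", "filtered", "filtered_p")


@dataclass
class ResponseRecord:
    """Fold-change pair and (optionally) the assigned response group."""

    phylotype: str
    fc_f_over_c: float | None  # top-down release; None when not computable
    fc_fp_over_f: float | None  # bottom-up release; None when not computable
    group: str = "NA"


@dataclass(frozen=True)
class ThresholdSpec:
    """Weak/strong response boundary.

    ``source`` is "fixed" for the literature default 1.3 and "derived"
    when recomputed as a percentile of the pooled fold-change values.
    """

    value: float = 1.3
    percentile: float = 25.0
    source: str = "fixed"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("threshold must be positive")
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")


def _safe_ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None:
        return None
    if not (math.isfinite(num) and math.isfinite(den)) or den <= 0:
        return None
    return num / den


def fold_changes(
    rate_table: GrowthRateTable,
    roles: Mapping[str, str] = DEFAULT_ROLES,
) -> list[ResponseRecord]:
    """Per-phylotype (F/C, F+P/F) fold changes of mean growth rates.

    A fold change is missing when its denominator rate is missing or
    non-positive; groups are left unset ("NA").
    """
    missing_roles = [r for r in _REQUIRED_ROLES if r not in roles]
    if missing_roles:
        raise ValueError(f"role map incomplete, missing: {missing_roles}")
    c, f, fp = roles["control"], roles["filtered"], roles["filtered_p"]
    pivot = rate_table.pivot()
    records = []
    for phylotype in pivot.index:
        mu = {
            t: (None if t not in pivot.columns or pd.isna(pivot.loc[phylotype, t])
                else float(pivot.loc[phylotype, t]))
            for t in (c, f, fp)
        }
        records.append(
            ResponseRecord(
                phylotype=str(phylotype),
                fc_f_over_c=_safe_ratio(mu[f], mu[c]),
                fc_fp_over_f=_safe_ratio(mu[fp], mu[f]),
            )
        )
    return records


def derive_threshold(
    records: Sequence[ResponseRecord],
    percentile: float = 25.0,
    column: str = "pooled",
) -> ThresholdSpec:
    """Percentile of the finite fold-change values (linear interpolation).

    ``column`` selects which distribution the percentile is taken over:
    "pooled" (both fold-change columns together, the default), "f_over_c",
    or "fp_over_f".
    """
    values: list[float] = []
    for rec in records:
        pair = {
            "f_over_c": rec.fc_f_over_c,
            "fp_over_f": rec.fc_fp_over_f,
        }
        if column == "pooled":
            picked = [v for v in pair.values() if v is not None]
        elif column in pair:
            picked = [pair[column]] if pair[column] is not None else []
        else:
            raise ValueError(f"unknown column {column!r}")
        values.extend(v for v in picked if math.isfinite(v))
    if len(values) < 4:
        raise ValueError(
            f"only {len(values)} finite fold-change value(s); "
            "too few to derive a percentile threshold — use a fixed one"
        )
    value = float(np.percentile(values, percentile, method="linear"))
    return ThresholdSpec(value=value, percentile=percentile, source="derived")


def classify_response(
    record: ResponseRecord, threshold: ThresholdSpec | float = ThresholdSpec()
) -> str:
    """Assign the response group for one fold-change pair.

    With T the threshold: both > T -> "I"; only F/C > T -> "II"; only
    F+P/F > T -> "III"; both <= T -> "NR"; either missing -> "NA".
    "Weak" is inclusive (<= T).
    """
    t = threshold.value if isinstance(threshold, ThresholdSpec) else float(threshold)
    if t <= 0:
        raise ValueError("threshold must be positive")
    fc1, fc2 = record.fc_f_over_c, record.fc_fp_over_f
    if fc1 is None or fc2 is None:
        return "NA"
    if fc1 > t and fc2 > t:
        return "I"
    if fc1 > t:
        return "II"
    if fc2 > t:
        return "III"
    return "NR"


def classify_records(
    records: Sequence[ResponseRecord],
    threshold: ThresholdSpec | float = ThresholdSpec(),
) -> list[ResponseRecord]:
    """Classify every record, returning new records with groups set."""
    return [
        ResponseRecord(
            phylotype=r.phylotype,
            fc_f_over_c=r.fc_f_over_c,
            fc_fp_over_f=r.fc_fp_over_f,
            group=classify_response(r, threshold),
        )
        for r in records
    ]


def aggregate_by_taxon(
    records: Sequence[ResponseRecord],
    taxonomy: TaxonomyTable,
    rank: str,
) -> pd.DataFrame:
    """Per-taxon mean fold changes and response-group composition.

    For each taxon at ``rank``: arithmetic mean of the finite values of
    each fold-change column over member phylotypes, member count, and the
    fraction of members per group label (fractions sum to 1 per taxon).
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy ranks {taxonomy.ranks}")
    rows = []
    by_taxon: dict[str, list[ResponseRecord]] = {}
    for rec in records:
        if rec.phylotype not in taxonomy.lineages.index:
            continue
        taxon = taxonomy.label(rec.phylotype, rank)
        by_taxon.setdefault(taxon, []).append(rec)
    for taxon, members in sorted(by_taxon.items()):
        fc1 = [m.fc_f_over_c for m in members if m.fc_f_over_c is not None]
        fc2 = [m.fc_fp_over_f for m in members if m.fc_fp_over_f is not None]
        row = {
            "taxon": taxon,
            "n_phylotypes": len(members),
            "mean_fc_f_over_c": float(np.mean(fc1)) if fc1 else math.nan,
            "mean_fc_fp_over_f": float(np.mean(fc2)) if fc2 else math.nan,
        }
        for g in GROUPS:
            n_g = sum(1 for m in members if m.group == g)
            row[f"n_{g}"] = n_g
            row[f"frac_{g}"] = n_g / len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def relative_share(
    counts: CountTable,
    metadata: Sequence[SampleMetadata],
    taxonomy: TaxonomyTable,
    rank: str,
    time_h: float,
) -> pd.DataFrame:
    """Percent of reads per taxon per treatment at one time point.

    Shares are computed per replicate over non-standard reads, then
    averaged across the replicates present at ``time_h``.  Output is a
    taxon × treatment matrix of percentages (columns sum to ~100).
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy ranks {taxonomy.ranks}")
    meta = metadata_frame(metadata)
    at_t = meta[meta["time_h"] == time_h]
    if at_t.empty:
        raise ValueError(f"no sample at time_h={time_h}")
    df = counts.counts.drop(index=[taxonomy.standard_id], errors="ignore")
    taxa = pd.Series(
        {
            p: taxonomy.label(p, rank)
            for p in df.index
            if p in taxonomy.lineages.index
        },
        name="taxon",
    )
    df = df.loc[taxa.index]

    shares_by_treatment: dict[str, pd.DataFrame] = {}
    for treatment, sub in at_t.groupby("treatment", sort=True):
        sample_ids = [s for s in sub.index if s in df.columns]
        if not sample_ids:
            continue
        block = df[sample_ids]
        per_rep = 100.0 * block.div(block.sum(axis=0), axis=1)
        taxon_share = per_rep.groupby(taxa).sum().mean(axis=1)
        shares_by_treatment[treatment] = taxon_share
    if not shares_by_treatment:
        raise ValueError(f"time point {time_h} h absent from all treatments")
    out = pd.DataFrame(shares_by_treatment).fillna(0.0)
    out.index.name = "taxon"
    return out
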