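"""Growth-rate estimation from normalized amplicon ratio curves.

The specific growth rate mu is the relative change of biomass B per unit
time, mu = dB/B * 1/dt.  For a phylotype growing exponentially the
spike-normalized read ratio r(t) is proportional to abundance, so
ln r(t) is linear in t with slope mu.  Each replicate bottle is fitted
separately by ordinary least squares of ln(ratio) on time (in days) over
the exponential window; fits are gated on R^2 and the per-phylotype rate
is the arithmetic mean of the passing replicate slopes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratios import GrowthCurveSet

__all__ = [
    "GrowthFit",
    "GrowthRateTable",
    "fit_exponential",
    "estimate_rates",
    "bulk_rates",
    "net_growth_from_counts",
    "compare_methods",
]

HOURS_PER_DAY = 24.0


@dataclass
class GrowthFit:
    """One log-linear fit of a replicate's ratio series."""

    phylotype: str
    treatment: str
    replicate: str
    mu_per_day: float  # slope of ln(ratio) vs time in days; nan if failed
    intercept: float  # ln(ratio) at t = 0; nan if failed
    r_squared: float  # nan if failed
    n_points: int
    passed: bool


def fit_exponential(
    times_h: Sequence[float],
    ratios: Sequence[float],
    window: tuple[float, float] = (0.0, 24.0),
    min_points: int = 3,
    r2_min: float = 0.6,
    phylotype: str = "",
    treatment: str = "",
    replicate: str = "",
) -> GrowthFit:
    """OLS fit of ln(ratio) against time (days) inside the closed window.

    Zero ratios inside the window are dropped before fitting (no
    pseudocount); a series left with fewer than ``min_points`` positive
    values is marked failed.  A fit passes iff r_squared > r2_min and at
    least ``min_points`` points were used.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape:
        raise ValueError("times and ratios must have equal length")
    lo, hi = window
    in_win = (t >= lo) & (t <= hi)
    pos = in_win & (r > 0)
    t_use = t[pos] / HOURS_PER_DAY
    y = np.log(r[pos])
    n = int(t_use.size)

    def _failed() -> GrowthFit:
        return GrowthFit(
            phylotype, treatment, replicate,
            mu_per_day=math.nan, intercept=math.nan, r_squared=math.nan,
            n_points=n, passed=False,
        )

    if n < max(min_points, 2) or np.unique(t_use).size < 2:
        return _failed()

    slope, intercept = np.polyfit(t_use, y, 1)
    fitted = slope * t_use + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # flat series: zero total variance means the line y = mean is exact
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    passed = bool(r2 > r2_min and n >= min_points)
    return GrowthFit(
        phylotype, treatment, replicate,
        mu_per_day=float(slope), intercept=float(intercept),
        r_squared=float(r2), n_points=n, passed=passed,
    )


@dataclass
class GrowthRateTable:
    """Replicate-averaged growth rates per phylotype × treatment.

    ``rates`` columns: phylotype, treatment, mean_mu (day^-1), sd_mu,
    n_replicates_passing.  Cells with no passing replicate are absent —
    missing is data, not zero.  ``fits`` keeps every individual replicate
    regression, passing or not.
    """

    rates: pd.DataFrame
    fits: list[GrowthFit]

    def mu(self, phylotype: str, treatment: str) -> float | None:
        sel = self.rates[
            (self.rates["phylotype"] == phylotype)
            & (self.rates["treatment"] == treatment)
        ]
        if sel.empty:
            return None
        return float(sel["mean_mu"].iloc[0])

    def pivot(self) -> pd.DataFrame:
        """phylotype × treatment matrix of mean rates (NaN = missing)."""
        return self.rates.pivot(
            index="phylotype", columns="treatment", values="mean_mu"
        )


def estimate_rates(
    curves: GrowthCurveSet,
    window: tuple[float, float] = (0.0, 24.0),
    r2_min: float = 0.6,
    min_points: int = 3,
    min_replicates: int = 1,
) -> GrowthRateTable:
    """Per-replicate log-linear fits, R^2-gated, averaged over replicates.

    Defaults follow standard practice for grazer-removal incubations:
    exponential window 0-24 h and an R^2 > 0.6 reliability gate.  The
    standard deviation is the sample SD (n-1) and is reported only when
    at least two replicates pass.
    """
    fits: list[GrowthFit] = []
    rows = []
    grouped = curves.data.groupby(["phylotype", "treatment"], sort=True)
    for (phylotype, treatment), sub in grouped:
        cell_fits = []
        for replicate, series in sub.groupby("replicate", sort=True):
            series = series.sort_values("time_h")
            fit = fit_exponential(
                series["time_h"].to_numpy(),
                series["ratio"].to_numpy(),
                window=window,
                min_points=min_points,
                r2_min=r2_min,
                phylotype=phylotype,
                treatment=treatment,
                replicate=str(replicate),
            )
            cell_fits.append(fit)
        fits.extend(cell_fits)
        passing = [f.mu_per_day for f in cell_fits if f.passed]
        if len(passing) >= min_replicates:
            rows.append(
                {
                    "phylotype": phylotype,
                    "treatment": treatment,
                    "mean_mu": float(np.mean(passing)),
                    "sd_mu": float(np.std(passing, ddof=1))
                    if len(passing) >= 2
                    else math.nan,
                    "n_replicates_passing": len(passing),
                }
            )
    rates = pd.DataFrame(
        rows,
        columns=["phylotype", "treatment", "mean_mu", "sd_mu", "n_replicates_passing"],
    )
    return GrowthRateTable(rates=rates, fits=fits)


def bulk_rates(
    rate_table: GrowthRateTable,
    quantiles: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> pd.DataFrame:
    """Community-level rate summary per treatment.

    Arithmetic mean and sample SD across rated phylotypes, plus the
    distribution quantiles used for violin-style summaries.  A treatment
    with a single rated phylotype reports SD as missing.
    """
    df = rate_table.rates
    if df.empty:
        raise ValueError("rate table is empty")
    rows = []
    for treatment, sub in df.groupby("treatment", sort=True):
        mus = sub["mean_mu"].to_numpy()
        if mus.size == 0:
            warnings.warn(f"treatment {treatment!r} has no rated phylotypes")
            continue
        row = {
            "treatment": treatment,
            "mean_mu": float(np.mean(mus)),
            "sd_mu": float(np.std(mus, ddof=1)) if mus.size >= 2 else math.nan,
            "n_phylotypes": int(mus.size),
        }
        for q in quantiles:
            row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(mus, q))
        rows.append(row)
    return pd.DataFrame(rows)


def net_growth_from_counts(
    n1: float, n2: float, t1_h: float, t2_h: float
) -> float:
    """Net growth rate (day^-1) between two absolute abundances.

    mu = ln(n2/n1) / ((t2 - t1)/24), the discrete form of
    mu = dB/B * 1/dt for exponential change between two time points.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell counts must be strictly positive")
    if t2_h <= t1_h:
        raise ValueError("t2_h must exceed t1_h")
    dt_days = (t2_h - t1_h) / HOURS_PER_DAY
    return math.log(n2 / n1) / dt_days


def compare_methods(
    arnis_rates: Mapping[str, float] | pd.Series,
    count_rates: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Pair ratio-based rates with microscopy count-based rates per group.

    Ratio-based rates track gene-copy number and can transiently exceed
    count-based rates under unbalanced growth (DNA replication running
    ahead of cell division).  Returns one row per shared group with the
    difference (ratio-based minus count-based); unmatched groups are
    listed in the DataFrame attribute ``attrs['unmatched']``.
    """
    a = pd.Series(dict(arnis_rates), dtype=float)
    c = pd.Series(dict(count_rates), dtype=float)
    shared = sorted(set(a.index) & set(c.index))
    if not shared:
        raise ValueError("no shared group labels between the two rate sets")
    out = pd.DataFrame(
        {
            "group": shared,
            "arnis_mu": a.loc[shared].to_numpy(),
            "count_mu": c.loc[shared].to_numpy(),
        }
    )
    out["difference"] = out["arnis_mu"] - out["count_mu"]
    out.attrs["unmatched"] = sorted(
        (set(a.index) | set(c.index)) - set(shared)
    )
    return out
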