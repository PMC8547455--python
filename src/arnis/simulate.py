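"""Synthetic amplicon time series for a grazer-removal / P-amendment design.

The generator emulates the statistical structure of a three-treatment
manipulation experiment: control (C), 1.2-um filtered (F, grazers
removed), and filtered + phosphate (F+P), each in triplicate bottles
sampled every ~12 h for 60 h and sequenced to ~127,000 reads per sample
with a constant-per-volume internal-standard spike.

Model per phylotype i and treatment:

* deterministic exponential abundance A_i(t) = A_i(0) * exp(mu_i * t/24),
  frozen after an optional stationary plateau (growth in such incubations
  is exponential only through roughly the first day);
* a phylotype-specific PCR-bias factor b_i, lognormal and constant
  across samples — the nuisance the spike-in normalization must cancel;
* the standard spiked at a fixed number of cells per ml of sample;
* reads drawn multinomially over (phylotypes + standard) with expected
  share proportional to b * cells, at a Normal library size.

All randomness flows through per-phylotype and per-sample substreams of
one seed, so adding a phylotype never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DEFAULT_ROLES, ResponseRecord
from .core import CountTable, SampleMetadata, TaxonomyTable
from .growth import GrowthRateTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedDataset",
    "RecoveryReport",
    "simulate_dataset",
    "recovery_report",
    "STANDARD_ID",
]

STANDARD_ID = "IS"

_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the reference study design.

    Growth-rate archetypes (all in day^-1): control rates are slow,
    U(0.1, 0.9); the filtered-treatment rate is control x a top-down
    release factor, strong (>1.3) for groups I and II, weak for III and
    NR, putting the majority of filtered rates in 0.6-3.5 with a fast
    tail above 4; the F+P rate is filtered x a bottom-up factor, strong
    for groups I and III, weak for II and NR.
    """

    n_phylotypes: int = 200
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.50, "II": 0.15, "III": 0.25, "NR": 0.10}
    )
    mu_control_range: tuple[float, float] = (0.1, 0.9)
    fc_filter_strong: tuple[float, float] = (1.8, 5.5)
    fc_filter_weak: tuple[float, float] = (0.7, 1.2)
    fc_phosphate_strong: tuple[float, float] = (1.4, 2.2)
    fc_phosphate_weak: tuple[float, float] = (0.5, 1.15)
    # physiological ceilings on the fastest bloomers; keep the spiked
    # standard quantifiable (>~0.1% of reads) at the latest time points
    mu_filter_cap: float = 4.5
    mu_phosphate_cap: float = 6.0  # >= 1.3 x mu_filter_cap keeps group-I
    # truth labels consistent with their own capped rates
    initial_abundance_log_mean: float = math.log(250.0)  # cells ml^-1
    initial_abundance_log_sigma: float = 0.8
    stationary_time_h: float | None = 24.0
    pcr_bias_sigma: float = 0.5
    reads_mean: float = 127018.0
    reads_sd: float = 15026.0
    reads_min: int = 1000
    standard_concentration_cells_per_ml: float = 2.0e8
    spike_volume_ul: float = 5.0
    sample_volume_ml: float = 100.0
    time_points_h: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0)
    n_replicates: int = 3
    treatments: tuple[str, str, str] = ("C", "F", "FP")  # control, filtered, filtered+P
    expectation_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"group proportions sum to {total}, expected 1")
        if self.n_phylotypes < 1:
            raise ValueError("need at least one phylotype")
        for name in (
            "reads_mean",
            "standard_concentration_cells_per_ml",
            "sample_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_volume_ul <= 0:
            raise ValueError("spike_volume_ul must be positive")

    @property
    def standard_cells_per_ml(self) -> float:
        """Spiked standard cells per ml of sample (concentration x spike
        volume / sample volume)."""
        return (
            self.standard_concentration_cells_per_ml
            * self.spike_volume_ul
            * 1e-3
            / self.sample_volume_ml
        )


@dataclass
class GroundTruth:
    """Simulator truth for recovery testing.

    ``phylotypes``: index phylotype id; columns group, mu_<treatment>
    (day^-1) per treatment, initial_abundance (cells ml^-1), bias.
    ``samples``: index sample id; standard_cells_per_ml, library_size.
    """

    phylotypes: pd.DataFrame
    samples: pd.DataFrame
    treatments: tuple[str, str, str]

    def true_mu(self, treatment: str) -> pd.Series:
        return self.phylotypes[f"mu_{treatment}"]


@dataclass
class SimulatedDataset:
    counts: CountTable
    metadata: list[SampleMetadata]
    taxonomy: TaxonomyTable
    truth: GroundTruth


_GROUP_ORDER = ("I", "II", "III", "NR")


def _phylotype_stream(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, i)))


def _sample_stream(seed: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, j)))


def _draw_phylotype(cfg: SyntheticConfig, i: int) -> dict:
    rng = _phylotype_stream(cfg.seed, i)
    groups = list(_GROUP_ORDER)
    probs = np.array([cfg.group_proportions.get(g, 0.0) for g in groups])
    group = rng.choice(groups, p=probs / probs.sum())
    mu_c = rng.uniform(*cfg.mu_control_range)
    fc1 = rng.uniform(
        *(cfg.fc_filter_strong if group in ("I", "II") else cfg.fc_filter_weak)
    )
    fc2 = rng.uniform(
        *(cfg.fc_phosphate_strong if group in ("I", "III") else cfg.fc_phosphate_weak)
    )
    mu_f = min(mu_c * fc1, cfg.mu_filter_cap)
    mu_fp = min(mu_f * fc2, cfg.mu_phosphate_cap)
    a0 = rng.lognormal(cfg.initial_abundance_log_mean, cfg.initial_abundance_log_sigma)
    bias = rng.lognormal(0.0, cfg.pcr_bias_sigma) if cfg.pcr_bias_sigma > 0 else 1.0
    c, f, fp = cfg.treatments
    return {
        "group": group,
        f"mu_{c}": mu_c,
        f"mu_{f}": mu_f,
        f"mu_{fp}": mu_fp,
        "initial_abundance": a0,
        "bias": bias,
    }


def _abundance(a0: float, mu: float, t_h: float, stationary_h: float | None) -> float:
    t_eff = t_h if stationary_h is None else min(t_h, stationary_h)
    return a0 * math.exp(mu * t_eff / 24.0)


def simulate_dataset(config: SyntheticConfig) -> SimulatedDataset:
    """Generate counts, metadata, taxonomy, and ground truth.

    Bit-for-bit reproducible from (config, seed).  In expectation mode the
    count table holds the exact expected (fractional) reads at the mean
    library size — no sampling noise — which makes pipeline identities
    exact and is used for bias-invariance fixtures.
    """
    cfg = config
    n = cfg.n_phylotypes
    ids = [f"P{i:04d}" for i in range(n)]
    truth_rows = {pid: _draw_phylotype(cfg, i) for i, pid in enumerate(ids)}
    phylo = pd.DataFrame.from_dict(truth_rows, orient="index")
    phylo.index.name = "phylotype_id"

    # The standard's own amplification bias is a single constant shared by
    # every sample: it rescales all ratios uniformly and cancels in every
    # slope, so the generator fixes it at 1 and keeps the spiked standard's
    # read share a direct function of community size.
    std_bias = 1.0
    std_cells = cfg.standard_cells_per_ml

    metadata: list[SampleMetadata] = []
    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    bias_vec = phylo["bias"].to_numpy()
    a0_vec = phylo["initial_abundance"].to_numpy()

    j = 0
    for treatment in cfg.treatments:
        mu_vec = phylo[f"mu_{treatment}"].to_numpy()
        for t_h in cfg.time_points_h:
            t_eff = (
                t_h
                if cfg.stationary_time_h is None
                else min(t_h, cfg.stationary_time_h)
            )
            cells = a0_vec * np.exp(mu_vec * t_eff / 24.0)
            weights = np.concatenate([bias_vec * cells, [std_bias * std_cells]])
            shares = weights / weights.sum()
            for rep in range(1, cfg.n_replicates + 1):
                sample_id = f"{treatment}_t{int(t_h):02d}_r{rep}"
                if cfg.expectation_mode:
                    reads = shares * cfg.reads_mean
                    library = float(cfg.reads_mean)
                else:
                    rng = _sample_stream(cfg.seed, j)
                    library = float(
                        np.round(
                            max(
                                cfg.reads_min,
                                rng.normal(cfg.reads_mean, cfg.reads_sd),
                            )
                        )
                    )
                    reads = rng.multinomial(int(library), shares).astype(np.int64)
                columns[sample_id] = reads
                metadata.append(
                    SampleMetadata(
                        sample_id=sample_id,
                        treatment=treatment,
                        time_h=float(t_h),
                        replicate=f"r{rep}",
                        sample_volume_ml=cfg.sample_volume_ml,
                        spike_volume_ul=cfg.spike_volume_ul,
                    )
                )
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "standard_cells_per_ml": std_cells,
                        "library_size": library,
                    }
                )
                j += 1

    count_df = pd.DataFrame(columns, index=ids + [STANDARD_ID])
    if not cfg.expectation_mode:
        count_df = count_df.astype(np.int64)
    counts = CountTable(count_df)

    taxonomy = _synthetic_taxonomy(ids)
    truth = GroundTruth(
        phylotypes=phylo,
        samples=pd.DataFrame(sample_rows).set_index("sample_id"),
        treatments=cfg.treatments,
    )
    return SimulatedDataset(counts, metadata, taxonomy, truth)


def _synthetic_taxonomy(ids: Sequence[str]) -> TaxonomyTable:
    """Placeholder ranked lineages: ~10 phylotypes per synthetic order."""
    rows = []
    for i, pid in enumerate(ids):
        rows.append(
            {
                "phylotype_id": pid,
                "domain": "Bacteria",
                "phylum": f"Phylum_{i // 50:02d}",
                "class": f"Class_{i // 25:02d}",
                "order": f"Order_{i // 10:02d}",
                "family": f"Family_{i // 5:03d}",
                "genus": f"Genus_{i:04d}",
            }
        )
    rows.append(
        {
            "phylotype_id": STANDARD_ID,
            "domain": "Bacteria",
            "phylum": "Proteobacteria",
            "class": "Betaproteobacteria",
            "order": "Burkholderiales",
            "family": "Comamonadaceae",
            "genus": "Limnohabitans",
        }
    )
    df = pd.DataFrame(rows).set_index("phylotype_id")[list(_RANKS)]
    return TaxonomyTable(df, standard_id=STANDARD_ID)


@dataclass
class RecoveryReport:
    """How well estimation recovered the simulator's truth."""

    per_treatment: pd.DataFrame  # rmse, mean_bias, pearson_r, n, coverage
    confusion: pd.DataFrame | None  # true group x predicted group counts
    label_accuracy: float | None

    def pearson_r(self, treatment: str) -> float:
        return float(
            self.per_treatment.loc[
                self.per_treatment["treatment"] == treatment, "pearson_r"
            ].iloc[0]
        )


def recovery_report(
    truth: GroundTruth,
    rate_table: GrowthRateTable,
    records: Sequence[ResponseRecord] | None = None,
) -> RecoveryReport:
    """Per-treatment RMSE / bias / Pearson r of estimated vs true rates,
    plus (when classified records are supplied) the group-label confusion
    matrix over records with a computable predicted label."""
    est = rate_table.pivot()
    shared = [p for p in est.index if p in truth.phylotypes.index]
    if not shared:
        raise ValueError("no phylotypes shared between truth and estimates")

    rows = []
    for treatment in truth.treatments:
        if treatment not in est.columns:
            continue
        e = est.loc[shared, treatment]
        t = truth.true_mu(treatment).loc[shared]
        ok = e.notna()
        n = int(ok.sum())
        n_total = len(truth.phylotypes)
        if n >= 2:
            diff = (e[ok] - t[ok]).to_numpy()
            r = float(stats.pearsonr(t[ok], e[ok]).statistic)
            rows.append(
                {
                    "treatment": treatment,
                    "rmse": float(np.sqrt(np.mean(diff**2))),
                    "mean_bias": float(np.mean(diff)),
                    "pearson_r": r,
                    "n": n,
                    "coverage": n / n_total,
                }
            )
        else:
            rows.append(
                {
                    "treatment": treatment,
                    "rmse": math.nan,
                    "mean_bias": math.nan,
                    "pearson_r": math.nan,
                    "n": n,
                    "coverage": n / n_total,
                }
            )
    per_treatment = pd.DataFrame(rows)

    confusion = None
    accuracy = None
    if records is not None:
        labeled = [
            r
            for r in records
            if r.group != "NA" and r.phylotype in truth.phylotypes.index
        ]
        if labeled:
            true_g = [truth.phylotypes.loc[r.phylotype, "group"] for r in labeled]
            pred_g = [r.group for r in labeled]
            labels = list(_GROUP_ORDER)
            confusion = pd.crosstab(
                pd.Categorical(true_g, categories=labels),
                pd.Categorical(pred_g, categories=labels),
                rownames=["true"],
                colnames=["predicted"],
                dropna=False,
            )
            accuracy = float(np.mean([t == p for t, p in zip(true_g, pred_g)]))
    return RecoveryReport(per_treatment, confusion, accuracy)
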