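"""End-to-end analysis pipeline: filter -> normalize -> fit -> classify.

``run_pipeline`` wires the library modules into one reproducible run that
reads the TSV inputs, writes every intermediate and final artifact as TSV
into an output directory, and records a JSON manifest (config hash, seed,
package version, artifact list) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_ROLES,
    ThresholdSpec,
    aggregate_by_taxon,
    classify_records,
    derive_threshold,
    fold_changes,
)
from .core import (
    DataError,
    read_count_table,
    read_metadata,
    read_taxonomy,
    validate_dataset,
)
from .diversity import bray_curtis_matrix, diversity_report
from .growth import bulk_rates, estimate_rates
from .ratios import FILTER_PRESETS, build_growth_curves, compute_arnis, filter_phylotypes

log = logging.getLogger("arnis")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-serializable)."""

    counts_path: str
    metadata_path: str
    taxonomy_path: str
    standard_id: str
    out_dir: str
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    filter_preset: str = "16S"  # key into FILTER_PRESETS, or "none"
    min_count: int | None = None  # explicit values override the preset
    min_sample_fraction: float | None = None
    window: tuple[float, float] = (0.0, 24.0)
    r2_min: float = 0.6
    min_points: int = 3
    min_replicates: int = 1
    threshold: float = 1.3
    derive_percentile: float | None = None  # derive T instead of fixed
    rank: str = "order"
    seed: int = 0

    def filter_params(self) -> tuple[int, float] | None:
        if self.min_count is not None and self.min_sample_fraction is not None:
            return self.min_count, self.min_sample_fraction
        if self.filter_preset == "none":
            return None
        if self.filter_preset not in FILTER_PRESETS:
            raise PipelineError(
                f"unknown filter preset {self.filter_preset!r}; "
                f"known: {sorted(FILTER_PRESETS)} or 'none'"
            )
        return FILTER_PRESETS[self.filter_preset]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (DataError, ValueError, OSError) as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: read -> prevalence filter -> validation -> ratio computation
    -> growth curves -> rate estimation -> fold changes -> classification
    -> bulk and diversity reports.  Every artifact is TSV; the manifest
    is JSON.  Deterministic given config and inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    counts = _stage("read_counts")(read_count_table)(config.counts_path)
    metadata = _stage("read_metadata")(read_metadata)(config.metadata_path)
    taxonomy = _stage("read_taxonomy")(read_taxonomy)(
        config.taxonomy_path, config.standard_id
    )

    params = config.filter_params()
    if params is not None:
        min_count, min_frac = params
        result = _stage("filter")(filter_phylotypes)(
            counts, min_count, min_frac, protected_ids=[config.standard_id]
        )
        log.info(
            "prevalence filter: %d -> %d phylotypes (%.1f%% removed, "
            "%.2f%% of reads)",
            result.n_phylotypes_before,
            result.n_phylotypes_after,
            100 * result.fraction_phylotypes_removed,
            100 * result.fraction_reads_removed,
        )
        counts = result.counts

    validated = _stage("validate")(validate_dataset)(counts, metadata, taxonomy)
    arnis_table = _stage("ratios")(compute_arnis)(validated)
    arnis_path = out / "ratios.tsv"
    arnis_table.ratios.to_csv(arnis_path, sep="\t", index_label="phylotype_id")
    artifacts["ratios"] = arnis_path.name

    curves = _stage("curves")(build_growth_curves)(arnis_table, metadata)
    rate_table = _stage("rates")(estimate_rates)(
        curves,
        window=config.window,
        r2_min=config.r2_min,
        min_points=config.min_points,
        min_replicates=config.min_replicates,
    )
    n_failed = sum(1 for f in rate_table.fits if not f.passed)
    log.info(
        "rate fits: %d total, %d failed the R^2/points gate",
        len(rate_table.fits),
        n_failed,
    )
    rates_path = out / "rates.tsv"
    rate_table.rates.to_csv(rates_path, sep="\t", index=False)
    artifacts["rates"] = rates_path.name

    bulk_path = out / "bulk_rates.tsv"
    _stage("bulk")(bulk_rates)(rate_table).to_csv(bulk_path, sep="\t", index=False)
    artifacts["bulk_rates"] = bulk_path.name

    records = _stage("fold_changes")(fold_changes)(rate_table, config.roles)
    if config.derive_percentile is not None:
        threshold = _stage("threshold")(derive_threshold)(
            records, config.derive_percentile
        )
    else:
        threshold = ThresholdSpec(value=config.threshold)
    records = classify_records(records, threshold)
    responses = pd.DataFrame(
        {
            "phylotype": [r.phylotype for r in records],
            "fc_f_over_c": [r.fc_f_over_c for r in records],
            "fc_fp_over_f": [r.fc_fp_over_f for r in records],
            "group": [r.group for r in records],
        }
    )
    resp_path = out / "responses.tsv"
    responses.to_csv(resp_path, sep="\t", index=False)
    artifacts["responses"] = resp_path.name
    log.info(
        "response groups (T=%.3g): %s",
        threshold.value,
        responses["group"].value_counts().to_dict(),
    )

    taxa_path = out / "taxon_responses.tsv"
    _stage("aggregate")(aggregate_by_taxon)(records, taxonomy, config.rank).to_csv(
        taxa_path, sep="\t", index=False
    )
    artifacts["taxon_responses"] = taxa_path.name

    shannon_path = out / "shannon.tsv"
    _stage("diversity")(diversity_report)(
        validated.counts, config.standard_id
    ).to_csv(shannon_path, sep="\t")
    artifacts["shannon"] = shannon_path.name
    bc_path = out / "bray_curtis.tsv"
    _stage("diversity")(bray_curtis_matrix)(
        validated.counts, config.standard_id
    ).to_csv(bc_path, sep="\t")
    artifacts["bray_curtis"] = bc_path.name

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "threshold": {
            "value": threshold.value,
            "percentile": threshold.percentile,
            "source": threshold.source,
        },
        "n_fits": len(rate_table.fits),
        "n_fits_failed_gate": n_failed,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
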