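import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from arnis import (
    CountTable,
    SampleMetadata,
    SyntheticConfig,
    TaxonomyTable,
    build_growth_curves,
    classify_records,
    compute_arnis,
    estimate_rates,
    fold_changes,
    simulate_dataset,
    validate_dataset,
)

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_bundle():
    """2 phylotypes + standard, 2 treatments x 2 times x 1 replicate."""
    counts = CountTable(
        pd.DataFrame(
            {
                "C_t00_r1": [100, 40, 200],
                "C_t24_r1": [120, 10, 180],
                "F_t00_r1": [100, 0, 250],
                "F_t24_r1": [400, 5, 125],
            },
            index=["P1", "P2", "IS"],
        )
    )
    metadata = [
        SampleMetadata("C_t00_r1", "C", 0.0, "r1"),
        SampleMetadata("C_t24_r1", "C", 24.0, "r1"),
        SampleMetadata("F_t00_r1", "F", 0.0, "r1"),
        SampleMetadata("F_t24_r1", "F", 24.0, "r1"),
    ]
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {
                "domain": ["Bacteria"] * 3,
                "order": ["O1", "O2", "Burkholderiales"],
                "genus": ["G1", "G2", "Limnohabitans"],
            },
            index=["P1", "P2", "IS"],
        ),
        standard_id="IS",
    )
    return counts, metadata, taxonomy


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic experiment, seed 1 (shared; treat as read-only)."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def sim_rates(sim_default):
    """Estimated rates for the shared synthetic experiment."""
    validated = validate_dataset(
        sim_default.counts, sim_default.metadata, sim_default.taxonomy
    )
    curves = build_growth_curves(compute_arnis(validated), sim_default.metadata)
    return estimate_rates(curves)


@pytest.fixture(scope="session")
def sim_records(sim_rates):
    """Classified response records for the shared synthetic experiment."""
    return classify_records(fold_changes(sim_rates), 1.3)
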