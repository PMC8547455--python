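"""Fold changes, threshold derivation, and response-group assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arnis import (
    GrowthRateTable,
    ResponseRecord,
    TaxonomyTable,
    ThresholdSpec,
    aggregate_by_taxon,
    classify_records,
    classify_response,
    derive_threshold,
    fold_changes,
    relative_share,
)


def _rate_table(mu_by_phylotype):
    """mu_by_phylotype: {phylotype: {treatment: mu or None}}"""
    rows = []
    for p, by_t in mu_by_phylotype.items():
        for t, mu in by_t.items():
            if mu is not None:
                rows.append(
                    {
                        "phylotype": p,
                        "treatment": t,
                        "mean_mu": mu,
                        "sd_mu": np.nan,
                        "n_replicates_passing": 3,
                    }
                )
    return GrowthRateTable(rates=pd.DataFrame(
        rows, columns=["phylotype", "treatment", "mean_mu", "sd_mu",
                       "n_replicates_passing"]), fits=[])


class TestFoldChanges:
    def test_ratios_of_rates(self):
        records = fold_changes(_rate_table({"P1": {"C": 1.0, "F": 3.0, "FP": 4.5}}))
        rec = records[0]
        assert rec.fc_f_over_c == pytest.approx(3.0)
        assert rec.fc_fp_over_f == pytest.approx(1.5)

    def test_missing_control_gives_missing_fold_change(self):
        records = fold_changes(_rate_table({"P1": {"C": None, "F": 3.0, "FP": 4.0}}))
        assert records[0].fc_f_over_c is None
        assert records[0].fc_fp_over_f == pytest.approx(4.0 / 3.0)

    def test_zero_denominator_gives_missing(self):
        records = fold_changes(_rate_table({"P1": {"C": 1.0, "F": 0.0, "FP": 2.0}}))
        assert records[0].fc_fp_over_f is None

    def test_incomplete_role_map_rejected(self):
        with pytest.raises(ValueError, match="filtered_p"):
            fold_changes(
                _rate_table({"P1": {"C": 1.0, "F": 2.0}}),
                roles={"control": "C", "filtered": "F"},
            )


class TestDeriveThreshold:
    @staticmethod
    def _records(values):
        return [
            ResponseRecord(f"P{i}", fc, None) for i, fc in enumerate(values)
        ]

    def test_constant_values_give_that_constant(self):
        spec = derive_threshold(self._records([2.0] * 6), 25, column="f_over_c")
        assert spec.value == pytest.approx(2.0)
        assert spec.source == "derived"

    def test_linear_interpolation_quartile(self):
        spec = derive_threshold(self._records([1.0, 2.0, 3.0, 4.0]), 25)
        assert spec.value == pytest.approx(1.75)

    def test_percentile_zero_is_minimum(self):
        spec = derive_threshold(self._records([0.4, 2.0, 3.0, 9.0]), 0)
        assert spec.value == pytest.approx(0.4)

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError, match="fixed"):
            derive_threshold(self._records([1.0, 2.0]), 25)

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=50.0),
            min_size=4,
            max_size=40,
        ),
        st.floats(min_value=0.0, max_value=100.0),
    )
    def test_matches_brute_force_sort_and_interpolate(self, values, pct):
        """Independent oracle: sort and linearly interpolate the order
        statistics by hand."""
        spec = derive_threshold(self._records(values), pct)
        xs = sorted(values)
        pos = pct / 100.0 * (len(xs) - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        expected = xs[lo] + (pos - lo) * (xs[hi] - xs[lo])
        assert spec.value == pytest.approx(expected, rel=1e-12, abs=1e-12)


def _oracle_group(fc1, fc2, t):
    """Independent re-statement of the four classification predicates."""
    strong_topdown = fc1 > t
    strong_bottomup = fc2 > t
    if strong_topdown and strong_bottomup:
        return "I"
    if strong_topdown and not strong_bottomup:
        return "II"
    if not strong_topdown and strong_bottomup:
        return "III"
    return "NR"


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "fc1,fc2,expected",
        [
            (5.36, 1.52, "I"),  # strong response to both manipulations
            (5.12, 1.07, "II"),  # grazing-released, P-indifferent
            (0.90, 2.98, "III"),  # P-stimulated, grazing-indifferent
            (1.0, 1.0, "NR"),
            (1.3, 1.3, "NR"),  # boundary is inclusive: <= T is weak
        ],
    )
    def test_group_assignment(self, fc1, fc2, expected):
        rec = ResponseRecord("p", fc1, fc2)
        assert classify_response(rec, 1.3) == expected

    def test_missing_fold_change_is_na(self):
        assert classify_response(ResponseRecord("p", None, 1.78), 1.3) == "NA"
        assert classify_response(ResponseRecord("p", 2.0, None), 1.3) == "NA"

    def test_partition_grid_matches_independent_predicates(self):
        """Brute-force enumeration over a (fc1, fc2) grid: the classifier
        agrees with an independent predicate implementation and always
        returns exactly one of the four finite-pair labels."""
        grid = np.round(np.arange(0.1, 5.01, 0.1), 10)
        for fc1 in grid:
            for fc2 in grid:
                got = classify_response(ResponseRecord("p", fc1, fc2), 1.3)
                assert got == _oracle_group(fc1, fc2, 1.3)
                assert got in {"I", "II", "III", "NR"}

    @given(
        st.floats(min_value=0.05, max_value=8.0),
        st.floats(min_value=0.05, max_value=8.0),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_common_rate_rescaling_leaves_groups_unchanged(self, mu_c, fc1, scale):
        """Scaling every rate by one positive constant preserves both fold
        changes and therefore the group label."""
        mu_f = mu_c * fc1
        mu_fp = mu_f * 1.7
        base = fold_changes(
            _rate_table({"P1": {"C": mu_c, "F": mu_f, "FP": mu_fp}})
        )[0]
        scaled = fold_changes(
            _rate_table(
                {"P1": {"C": scale * mu_c, "F": scale * mu_f, "FP": scale * mu_fp}}
            )
        )[0]
        assert scaled.fc_f_over_c == pytest.approx(base.fc_f_over_c, rel=1e-9)
        assert scaled.fc_fp_over_f == pytest.approx(base.fc_fp_over_f, rel=1e-9)
        assert classify_response(scaled, 1.3) == classify_response(base, 1.3)


@pytest.fixture
def small_taxonomy():
    return TaxonomyTable(
        pd.DataFrame(
            {
                "domain": ["Bacteria"] * 4,
                "order": ["O1", "O1", "O1", "Burkholderiales"],
            },
            index=["P1", "P2", "P3", "IS"],
        ),
        standard_id="IS",
    )


class TestAggregateByTaxon:
    def test_group_fractions(self, small_taxonomy):
        records = [
            ResponseRecord("P1", 2.0, 2.0, "I"),
            ResponseRecord("P2", 3.0, 2.0, "I"),
            ResponseRecord("P3", 1.0, 2.0, "III"),
        ]
        out = aggregate_by_taxon(records, small_taxonomy, "order")
        row = out[out["taxon"] == "O1"].iloc[0]
        assert row["frac_I"] == pytest.approx(2 / 3)
        assert row["frac_III"] == pytest.approx(1 / 3)
        assert row["mean_fc_f_over_c"] == pytest.approx(2.0)

    def test_singleton_taxon_means_equal_member(self, small_taxonomy):
        records = [ResponseRecord("P1", 4.2, 0.7, "II")]
        out = aggregate_by_taxon(records, small_taxonomy, "order")
        row = out.iloc[0]
        assert row["mean_fc_f_over_c"] == pytest.approx(4.2)
        assert row["mean_fc_fp_over_f"] == pytest.approx(0.7)

    def test_fractions_sum_to_one(self, small_taxonomy):
        records = [
            ResponseRecord("P1", 2.0, 2.0, "I"),
            ResponseRecord("P2", None, 2.0, "NA"),
            ResponseRecord("P3", 1.0, 1.0, "NR"),
        ]
        out = aggregate_by_taxon(records, small_taxonomy, "order")
        frac_cols = [c for c in out.columns if c.startswith("frac_")]
        assert out[frac_cols].sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_unknown_rank_rejected(self, small_taxonomy):
        with pytest.raises(ValueError, match="genus"):
            aggregate_by_taxon([], small_taxonomy, "genus")


class TestRelativeShare:
    def test_shares_computed_and_sum_to_100(self, toy_bundle):
        counts, metadata, taxonomy = toy_bundle
        out = relative_share(counts, metadata, taxonomy, "order", 24.0)
        assert set(out.columns) == {"C", "F"}
        # C at 24 h: P1=120, P2=10 -> O1 92.3%, O2 7.7%
        assert out.loc["O1", "C"] == pytest.approx(100 * 120 / 130)
        assert out.sum(axis=0).loc["C"] == pytest.approx(100.0)
        assert out.sum(axis=0).loc["F"] == pytest.approx(100.0)

    def test_absent_time_point_rejected(self, toy_bundle):
        counts, metadata, taxonomy = toy_bundle
        with pytest.raises(ValueError, match="99"):
            relative_share(counts, metadata, taxonomy, "order", 99.0)
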