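"""GEBVs, standardization, the weighted selection index and donor lists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agscreen import (
    DEFAULT_INDEX_WEIGHTS,
    InputDataError,
    MixedModel,
    SelectionIndexScorer,
    compute_grm,
    donor_report,
    gblup_gebvs,
    select_donors,
    selection_index,
    standardize_gebvs,
)
from agscreen.datasets import load_example_donor_table
from agscreen.phenotypes import TRAITS, plots_to_traits
from agscreen.simulate import TrialSimulator

from conftest import small_config


@pytest.fixture(scope="module")
def small_trial():
    cfg = small_config(rng_seed=5)
    result = TrialSimulator(cfg).run()
    table = plots_to_traits(result.plots)
    grm = compute_grm(result.panel, ridge=0.0)
    return result, table, grm


class TestGEBVs:
    def test_identity_kinship_reduces_to_phenotypic_blups(self, small_trial):
        result, table, grm = small_trial
        identity = pd.DataFrame(
            np.eye(len(grm.genotype_ids)),
            index=grm.genotype_ids, columns=grm.genotype_ids,
        )
        sub = table[table.condition == "anaerobic"]
        gebvs = gblup_gebvs(sub, type(grm)(grm.genotype_ids, identity.to_numpy(),
                                           denominator=np.nan),
                            environment="anaerobic", traits=("germ14_pct",))
        pheno = MixedModel(scope="across").fit(sub[sub.trait == "germ14_pct"])
        np.testing.assert_allclose(
            gebvs["germ14_pct"].reindex(pheno.predict().index),
            pheno.predict(), atol=1e-8,
        )

    def test_every_panel_genotype_appears_once(self, small_trial):
        _, table, grm = small_trial
        gebvs = gblup_gebvs(table, grm, environment="across",
                            traits=("germ14_pct", "germ21_pct"))
        assert list(gebvs.index) == list(grm.genotype_ids)

    def test_germination_gebvs_live_on_percentage_scale(self, small_trial):
        _, table, grm = small_trial
        gebvs = gblup_gebvs(table[table.condition == "anaerobic"], grm,
                            environment="anaerobic", traits=("germ14_pct",))
        assert 5 < gebvs["germ14_pct"].mean() < 70

    def test_large_panel_mismatch_raises(self, small_trial):
        _, table, grm = small_trial
        shrunk = type(grm)(grm.genotype_ids[:5],
                           grm.values[:5, :5], denominator=grm.denominator)
        with pytest.raises(InputDataError, match="panel"):
            gblup_gebvs(table, shrunk, environment="across",
                        traits=("germ14_pct",))


class TestStandardization:
    def test_columns_standardized(self):
        rng = np.random.default_rng(2)
        gebvs = pd.DataFrame(rng.normal(5, 3, size=(40, 3)),
                             columns=["a", "b", "c"])
        std, flags = standardize_gebvs(gebvs)
        np.testing.assert_allclose(std.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(std.std(ddof=1), 1.0, atol=1e-10)
        assert flags == []

    def test_zero_variance_trait_flagged_as_zeros(self):
        gebvs = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        std, flags = standardize_gebvs(gebvs)
        assert flags == ["b"]
        np.testing.assert_allclose(std["b"], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        gebvs = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        once, _ = standardize_gebvs(gebvs)
        twice, _ = standardize_gebvs(once)
        pd.testing.assert_frame_equal(twice, once, atol=1e-10)

    def test_single_genotype_rejected(self):
        with pytest.raises(InputDataError):
            standardize_gebvs(pd.DataFrame({"a": [1.0]}))


class TestSelectionIndex:
    def test_null_weights_rejected_but_zero_index_from_zero_values(self):
        std = pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"])
        idx = selection_index(std, {"a": 1.0, "b": 2.0})
        np.testing.assert_allclose(idx, 0.0)
        with pytest.raises(InputDataError):
            selection_index(std, {"a": 0.0, "b": 0.0})

    def test_single_weight_projects_one_trait(self):
        rng = np.random.default_rng(4)
        std = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        idx = selection_index(std, {"b": 1.0})
        np.testing.assert_allclose(idx, std["b"])

    def test_weighted_sum_matches_hand_oracle(self):
        std = pd.DataFrame(
            [[1.0, 0.5, -1.0, 0.0, 2.0, 1.0, -0.5, 0.3]] * 5,
            columns=list(TRAITS),
            index=[f"g{i}" for i in range(5)],
        )
        idx = selection_index(std, DEFAULT_INDEX_WEIGHTS)
        w = DEFAULT_INDEX_WEIGHTS
        expected = sum(w[t] * std.iloc[0][t] for t in TRAITS)
        np.testing.assert_allclose(idx, expected, atol=1e-12)

    def test_missing_weighted_trait_flags_index(self):
        std = pd.DataFrame({"germ14_pct": [1.0, np.nan], "germ21_pct": [0.5, 0.5]})
        idx = selection_index(std, {"germ14_pct": 2.0, "germ21_pct": 1.0})
        assert np.isnan(idx.iloc[1]) and np.isfinite(idx.iloc[0])

    def test_invariant_to_constant_shift_of_one_trait(self):
        rng = np.random.default_rng(6)
        gebvs = pd.DataFrame(rng.normal(size=(30, 8)), columns=list(TRAITS))
        scorer = SelectionIndexScorer()
        idx0 = scorer.fit(gebvs).predict(gebvs)
        shifted = gebvs.assign(germ14_pct=gebvs["germ14_pct"] + 55.0)
        idx1 = SelectionIndexScorer().fit(shifted).predict(shifted)
        np.testing.assert_allclose(idx1, idx0, atol=1e-9)


class TestSelectDonors:
    def test_strict_threshold_conjunction(self):
        idx = pd.Series({"a": 24.9, "b": 30.0, "c": 26.0})
        germ = pd.Series({"a": 95.0, "b": 69.9, "c": 75.0})
        out = select_donors(idx, germ, rule="anaerobic")
        assert list(out["genotype"]) == ["c"]

    def test_empty_input_is_valid(self):
        out = select_donors(pd.Series(dtype=float), pd.Series(dtype=float),
                            rule="across")
        assert len(out) == 0

    def test_sorted_by_index_then_germination_then_label(self):
        idx = pd.Series({"a": 30.0, "b": 30.0, "c": 40.0, "d": 30.0})
        germ = pd.Series({"a": 80.0, "b": 90.0, "c": 75.0, "d": 80.0})
        out = select_donors(idx, germ, rule="anaerobic")
        assert list(out["genotype"]) == ["c", "b", "a", "d"]

    def test_checks_flagged_but_retained(self):
        idx = pd.Series({"CHK01": 50.0, "ENT001": 40.0})
        germ = pd.Series({"CHK01": 90.0, "ENT001": 85.0})
        out = select_donors(idx, germ, rule="anaerobic", checks={"CHK01"})
        assert out.set_index("genotype")["is_check"].to_dict() == {
            "CHK01": True, "ENT001": False
        }

    @settings(derandomize=True, max_examples=30)
    @given(idx_min=st.floats(0, 60), germ_min=st.floats(0, 100))
    def test_threshold_monotonicity(self, idx_min, germ_min):
        rng = np.random.default_rng(9)
        idx = pd.Series(rng.uniform(0, 60, 50), index=[f"g{i}" for i in range(50)])
        germ = pd.Series(rng.uniform(0, 100, 50), index=idx.index)
        base = set(select_donors(idx, germ, "anaerobic", 25.0, 70.0)["genotype"])
        tighter = set(
            select_donors(idx, germ, "anaerobic",
                          max(25.0, idx_min), max(70.0, germ_min))["genotype"]
        )
        assert tighter <= base


class TestDonorReport:
    def test_published_shape_table_row_counts(self):
        # re-filtering a published donor table with the printed rules keeps
        # every row; 10/13/17 test entries plus flagged checks
        table = load_example_donor_table()
        checks = set(table.loc[table.remarks == "Check", "genotype"])
        expected_entries = {"anaerobic": 10, "aerobic": 13, "across": 17}
        for rule, n_entries in expected_entries.items():
            sub = table[table.condition == rule].set_index("genotype")
            out = select_donors(sub["selection_index"], sub["germ21_blup_pct"],
                                rule=rule, checks=checks)
            assert len(out) == len(sub)
            assert int((~out["is_check"]).sum()) == n_entries

    def test_report_files_and_determinism(self, tmp_path):
        idx = pd.Series({"CHK01": 43.0, "ENT001": 46.0, "ENT002": 31.0})
        germ = pd.Series({"CHK01": 79.0, "ENT001": 75.0, "ENT002": 74.0})
        lists = {
            "anaerobic": select_donors(idx, germ, "anaerobic", checks={"CHK01"})
        }
        paths = donor_report(lists, tmp_path / "a")
        content = paths[0].read_text()
        assert content.count("\n") == 4  # header + 3 rows
        assert "Check" in content and "Entry" in content
        paths2 = donor_report(lists, tmp_path / "b")
        assert paths2[0].read_bytes() == paths[0].read_bytes()
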