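"""Response indices, cumulative scores and SD-band classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saltscreen as ss
from saltscreen.ssri import IndexError_

from conftest import table_from_means


class TestResponseIndices:
    def test_identity_ratio(self):
        cells = {("g1", s, t): 17.3 for s in ("control", "moderate", "high")
                 for t in ("PH", "TRL")}
        idx = ss.response_indices(ss.aggregate_means(table_from_means(cells)), ["PH", "TRL"])
        assert (idx["issri_moderate"] == 1.0).all()
        assert (idx["issri_high"] == 1.0).all()

    def test_chlorophyll_rise_under_moderate_stress(self):
        # mean chlorophyll rises 21.4 -> 24.9 under moderate stress: ratio > 1 is kept
        cells = {("g1", "control", "CH"): 21.4, ("g1", "moderate", "CH"): 24.9,
                 ("g1", "high", "CH"): 19.7}
        idx = ss.response_indices(ss.aggregate_means(table_from_means(cells)), ["CH"])
        assert idx["issri_moderate"].iloc[0] == pytest.approx(1.1636, abs=5e-5)

    def test_zero_control_is_an_error_naming_the_cell(self):
        cells = {("g1", "control", "PH"): 0.0, ("g1", "moderate", "PH"): 5.0,
                 ("g1", "high", "PH"): 2.0}
        with pytest.raises(IndexError_, match="'g1'.*'PH'"):
            ss.response_indices(ss.aggregate_means(table_from_means(cells)), ["PH"])

    def test_missing_cell_is_an_error(self):
        cells = {("g1", "control", "PH"): 10.0, ("g1", "moderate", "PH"): 5.0}
        with pytest.raises(IndexError_):
            ss.response_indices(ss.aggregate_means(table_from_means(cells)), ["PH"])


class TestCumulativeIndices:
    def test_no_stress_effect_bound(self, no_effect_means):
        idx = ss.response_indices(no_effect_means, "eq3-20")
        scores = ss.cumulative_indices(idx, "eq3-20")
        assert (scores["cmssri"] == 20).all()
        assert (scores["chssri"] == 20).all()
        assert (scores["tssri"] == 40).all()

    def test_two_trait_toy_sums(self, two_trait_means):
        idx = ss.response_indices(two_trait_means, ["PH", "TRL"])
        scores = ss.cumulative_indices(idx, ["PH", "TRL"])
        assert scores.loc["g1", "cmssri"] == pytest.approx(1.3)
        assert scores.loc["g1", "chssri"] == pytest.approx(0.65)
        assert scores.loc["g1", "tssri"] == pytest.approx(1.95)

    def test_total_is_exact_sum_of_levels(self, small_trial):
        table, _ = small_trial
        idx = ss.response_indices(ss.aggregate_means(table), "eq3-20")
        scores = ss.cumulative_indices(idx, "eq3-20")
        assert (scores["tssri"] == scores["cmssri"] + scores["chssri"]).all()

    def test_missing_trait_in_index_table_reported(self, two_trait_means):
        idx = ss.response_indices(two_trait_means, ["PH"])
        with pytest.raises(IndexError_, match="TRL"):
            ss.cumulative_indices(idx, ["PH", "TRL"])


class TestGroupIndices:
    def test_shoot_subindex_on_no_effect_data(self, no_effect_means):
        idx = ss.response_indices(no_effect_means, "eq3-20")
        scores = ss.cumulative_indices(idx, "eq3-20")
        # 6 shoot traits x 2 stress levels, all ratios 1
        assert (ss.group_indices(scores, "shoot") == 12).all()

    def test_categories_partition_total(self, small_trial):
        table, _ = small_trial
        idx = ss.response_indices(ss.aggregate_means(table), "eq3-20")
        scores = ss.cumulative_indices(idx, "eq3-20")
        total = sum(ss.group_indices(scores, c) for c in ("shoot", "root", "physiological"))
        np.testing.assert_allclose(total, scores["tssri"], rtol=1e-12)

    def test_two_trait_toy_by_category(self):
        cells = {("g1", "control", "PH"): 10.0, ("g1", "moderate", "PH"): 5.0,
                 ("g1", "high", "PH"): 5.0,
                 ("g1", "control", "TRL"): 10.0, ("g1", "moderate", "TRL"): 5.0,
                 ("g1", "high", "TRL"): 5.0}
        scores = ss.cumulative_indices(
            ss.response_indices(ss.aggregate_means(table_from_means(cells)), ["PH", "TRL"]),
            ["PH", "TRL"])
        assert ss.group_indices(scores, "shoot").iloc[0] == pytest.approx(1.0)
        assert ss.group_indices(scores, "root").iloc[0] == pytest.approx(1.0)
        assert scores["tssri"].iloc[0] == pytest.approx(2.0)

    def test_unknown_category_raises(self, two_trait_means):
        idx = ss.response_indices(two_trait_means, ["PH", "TRL"])
        scores = ss.cumulative_indices(idx, ["PH", "TRL"])
        with pytest.raises(KeyError):
            ss.group_indices(scores, "stem")


class TestClassifyTssri:
    def test_published_screen_boundaries_and_extremes(self):
        t2 = ss.datasets.load_tssri_table()
        cls = ss.classify_tssri(t2.set_index("genotype")["tssri"])
        assert cls.min_tssri == 25.15
        assert t2["tssri"].max() == 39.87
        assert t2.loc[t2["tssri"].idxmax(), "genotype"] == "FED 473"
        assert t2.loc[t2["tssri"].idxmin(), "genotype"] == "IR85427"
        assert cls.b1 == pytest.approx(26.54, abs=0.005)
        assert cls.classes["FED 473"] == "high"

    def test_published_band_edges_give_seven_sensitive(self):
        t2 = ss.datasets.load_tssri_table()
        pb = ss.datasets.PRINTED_BOUNDARIES
        classes = ss.classify_by_boundaries(t2["tssri"], pb["b1"], pb["b2"], pb["b3"])
        counts = classes.value_counts()
        assert counts["sensitive"] == 7
        assert counts["low"] == 27

    def test_boundary_straddler_goes_to_low(self):
        # 26.75 exceeds the sensitive ceiling 26.54, so the rule says low
        pb = ss.datasets.PRINTED_BOUNDARIES
        cls = ss.classify_by_boundaries(pd.Series([26.75]), pb["b1"], pb["b2"], pb["b3"])
        assert cls.iloc[0] == "low"

    def test_degenerate_zero_sd(self):
        cls = ss.classify_tssri(pd.Series([30.0, 30.0, 30.0]))
        assert cls.sd_tssri == 0
        assert cls.b1 == cls.b2 == cls.b3 == 30.0
        assert (cls.classes == "sensitive").all()

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError, match="2 genotypes"):
            ss.classify_tssri(pd.Series([30.0]))

    def test_order_invariance(self):
        t2 = ss.datasets.load_tssri_table()
        s = pd.Series(t2["tssri"].to_numpy(), index=range(len(t2)))
        a = ss.classify_tssri(s)
        b = ss.classify_tssri(s.sample(frac=1, random_state=3))
        assert a.counts == b.counts
        assert (a.classes.sort_index() == b.classes.sort_index()).all()


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(min_value=0.05, max_value=3.0), min_size=2, max_size=8),
       st.floats(min_value=1.01, max_value=2.0))
def test_scaling_stressed_means_up_strictly_increases_tssri(ratios, factor):
    """Raising every stressed mean of a genotype (controls fixed) raises its TSSRI."""
    traits = ["PH", "TN", "LA", "LW", "SW", "RW", "TW", "LRL"][: len(ratios)]
    cells = {}
    for t, r in zip(traits, ratios):
        cells[("g1", "control", t)] = 10.0
        cells[("g1", "moderate", t)] = 10.0 * r
        cells[("g1", "high", t)] = 10.0 * r * 0.5
    base = ss.cumulative_indices(
        ss.response_indices(ss.aggregate_means(table_from_means(cells)), traits), traits)
    scaled_cells = {k: (v * factor if k[1] != "control" else v) for k, v in cells.items()}
    scaled = ss.cumulative_indices(
        ss.response_indices(ss.aggregate_means(table_from_means(scaled_cells)), traits), traits)
    assert scaled.loc["g1", "tssri"] > base.loc["g1", "tssri"]
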