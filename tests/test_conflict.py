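import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tigerocc.conflict import (
    Thresholds, TwoByTwo, build_table, classify_subgrids, homogeneity_test,
    log_or_test, marginal_association, naive_occupancy, odds_ratio,
    rescue_presence, thresholds_from_data,
)
from tigerocc.published import (
    PREY_BY_POPULATION_STRATA, PREY_USE_TABLE, POPULATION_TABLE,
    TIGER_USE_TABLE, write_conflict_fixture,
)

cells = st.integers(min_value=1, max_value=500)
tables = st.builds(TwoByTwo, cells, cells, cells, cells)


class TestOddsRatio:
    def test_cross_product(self):
        assert odds_ratio(TwoByTwo(13, 3, 208, 183)) == pytest.approx(3.8125)
        assert odds_ratio(TwoByTwo(8, 2, 63, 173)) == pytest.approx(
            10.984127, abs=1e-5)
        assert odds_ratio(TwoByTwo(1, 1, 1, 1)) == 1.0

    def test_zero_cell_needs_continuity(self):
        t = TwoByTwo(0, 3, 10, 5)
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio(t)
        assert odds_ratio(t, continuity=True) == pytest.approx(
            (0.5 * 5.5) / (3.5 * 10.5))

    @settings(derandomize=True, max_examples=50)
    @given(tables)
    def test_exposure_swap_inverts(self, t):
        assert odds_ratio(t) * odds_ratio(t.swap_exposure()) == \
            pytest.approx(1.0, rel=1e-9)


class TestLogOrTest:
    @pytest.mark.parametrize("cells,log_or,z,p", [
        ((13, 3, 208, 183), 1.338, 2.064, 0.020),   # prey use
        ((11, 5, 197, 194), 0.773, 1.409, 0.079),   # tiger use
        ((10, 6, 236, 155), 0.0904, 0.172, 0.432),  # population
    ])
    def test_reported_triples(self, cells, log_or, z, p):
        res = log_or_test(TwoByTwo(*cells), alternative="greater")
        assert res.log_or == pytest.approx(log_or, abs=5e-4)
        assert res.z == pytest.approx(z, abs=5e-4)
        assert res.p == pytest.approx(p, abs=5e-4)

    def test_se_formula(self):
        res = log_or_test(TwoByTwo(13, 3, 208, 183))
        assert res.se == pytest.approx(
            np.sqrt(1 / 13 + 1 / 3 + 1 / 208 + 1 / 183), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(tables)
    def test_antisymmetry_and_p_complement(self, t):
        fwd = log_or_test(t, "greater")
        rev = log_or_test(t.swap_exposure(), "greater")
        assert fwd.z == pytest.approx(-rev.z, rel=1e-9, abs=1e-12)
        assert log_or_test(t, "greater").p + log_or_test(t, "less").p == \
            pytest.approx(1.0, abs=1e-12)

    def test_two_sided_doubles_tail(self):
        t = TwoByTwo(13, 3, 208, 183)
        assert log_or_test(t, "two_sided").p == pytest.approx(
            2 * log_or_test(t, "greater").p, rel=1e-12)


class TestHomogeneity:
    def test_identical_strata_give_zero(self):
        t = TwoByTwo(5, 3, 10, 12)
        res = homogeneity_test([("a", t), ("b", t)])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_stratum_order_invariance(self):
        strata = list(PREY_BY_POPULATION_STRATA)
        res1 = homogeneity_test(strata)
        res2 = homogeneity_test(strata[::-1])
        assert res1.chi2 == pytest.approx(res2.chi2, rel=1e-12)

    def test_agrees_with_direct_formula_on_reported_strata(self):
        """Independent inline evaluation of the inverse-variance chi-square
        on the published stratified tables."""
        lors, ws = [], []
        for _, t in PREY_BY_POPULATION_STRATA:
            lors.append(np.log((t.a * t.d) / (t.b * t.c)))
            ws.append(1 / (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d))
        lors, ws = np.array(lors), np.array(ws)
        pooled = (ws * lors).sum() / ws.sum()
        expected = float((ws * (lors - pooled) ** 2).sum())
        res = homogeneity_test(PREY_BY_POPULATION_STRATA)
        assert res.chi2 == pytest.approx(expected, rel=1e-12)
        # the evidence for heterogeneous odds ratios is strong
        assert res.p < 0.05

    def test_equal_or_strata_give_zero_even_if_counts_differ(self):
        # both strata have OR = 2 exactly
        strata = [("a", TwoByTwo(4, 2, 10, 10)), ("b", TwoByTwo(8, 4, 5, 5))]
        res = homogeneity_test(strata)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_breslow_day_option_runs_and_flags_heterogeneity(self):
        res = homogeneity_test(PREY_BY_POPULATION_STRATA,
                               method="breslow-day")
        assert res.method == "breslow-day"
        assert res.p < 0.05

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="2 strata"):
            homogeneity_test([("only", TwoByTwo(1, 2, 3, 4))])


class TestMarginalAssociation:
    def test_reported_prey_by_population_margin(self):
        table, or_ = marginal_association(PREY_BY_POPULATION_STRATA)
        assert (table.a, table.b, table.c, table.d) == (150, 71, 11, 175)
        assert or_ == pytest.approx(33.61, abs=0.01)

    def test_identical_margins_give_unit_or(self):
        strata = [("a", TwoByTwo(3, 2, 7, 8)), ("b", TwoByTwo(2, 3, 8, 7))]
        table, or_ = marginal_association(strata)
        assert or_ == pytest.approx(1.0)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            marginal_association([("a", TwoByTwo(1, 1, 1, 1)),
                                  ("b", TwoByTwo(0, 0, 0, 0))])


class TestNaiveOccupancy:
    def test_reported_value(self):
        assert naive_occupancy(36, 57) == pytest.approx(0.63, abs=0.005)

    @pytest.mark.parametrize("det,sur,expected", [(0, 57, 0.0), (57, 57, 1.0)])
    def test_bounds(self, det, sur, expected):
        assert naive_occupancy(det, sur) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            naive_occupancy(1, 0)
        with pytest.raises(ValueError):
            naive_occupancy(5, 3)


class TestClassification:
    def _frame(self):
        idx = pd.Index([f"s{i}" for i in range(6)], name="subgrid_id")
        use = pd.DataFrame({
            "p_tiger_use": [0.54, 0.55, 0.2, 0.9, 0.6, 0.1],
            "p_prey_use": [0.85, 0.80, 0.1, 0.95, 0.5, 0.81],
            "in_buffer": [True, True, True, True, False, True],
        }, index=idx)
        pop = pd.Series([100, 200, 141, 500, 50, 142.0], index=idx)
        return use, pop

    def test_strict_inequality_at_threshold(self):
        use, pop = self._frame()
        labels = classify_subgrids(use, pop, Thresholds(), buffer_only=False)
        assert not labels.loc["s0", "high_tiger"]   # exactly 0.54 -> low
        assert labels.loc["s1", "high_tiger"]
        assert not labels.loc["s1", "high_prey"]    # exactly 0.80 -> low
        assert not labels.loc["s2", "high_pop"]     # exactly 141 -> low
        assert labels.loc["s5", "high_pop"]

    def test_buffer_only_drops_cells(self):
        use, pop = self._frame()
        labels = classify_subgrids(use, pop, buffer_only=True)
        assert "s4" not in labels.index
        assert len(labels) == 5

    def test_mismatched_cells_rejected(self):
        use, pop = self._frame()
        with pytest.raises(ValueError, match="different cells"):
            classify_subgrids(use, pop.iloc[:-1], buffer_only=False)

    def test_thresholds_recomputable_from_data(self):
        use, pop = self._frame()
        th = thresholds_from_data(use, pop)
        assert th.tiger_use_cut == pytest.approx(use["p_tiger_use"].mean())
        assert th.pop_cut == pytest.approx(pop.mean())


class TestBuildTable:
    def test_counts_cells_not_events(self):
        idx = pd.Index(["a", "b", "c", "d"], name="subgrid_id")
        exposure = pd.Series([True, True, False, False], index=idx)
        rescues = pd.DataFrame({
            "date": pd.to_datetime(["2021-01-01"] * 3),
            "subgrid_id": ["a", "a", "c"],   # two rescues in one cell
            "sex": "male", "age_class": "adult",
        })
        events = rescue_presence(rescues, idx)
        t = build_table(exposure, events)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.total == len(idx)

    def test_no_events(self):
        idx = pd.Index(["a", "b"], name="subgrid_id")
        t = build_table(pd.Series([True, False], index=idx),
                        pd.Series([False, False], index=idx))
        assert (t.a, t.b) == (0, 0)

    def test_fixture_reproduces_published_tables(self, tmp_path):
        """The packaged cell-level reconstruction reproduces every published
        marginal and stratified table through the classify/tabulate path."""
        from tigerocc.survey_data import load_rescues
        paths = write_conflict_fixture(tmp_path)
        use = pd.read_csv(paths["use_map"]).set_index("subgrid_id")
        pop = pd.read_csv(paths["population"]).set_index("subgrid_id")["population"]
        rescues = load_rescues(paths["rescues"])
        labels = classify_subgrids(use, pop, buffer_only=True)
        events = rescue_presence(rescues, labels.index)
        assert build_table(labels["high_tiger"], events) == TIGER_USE_TABLE
        assert build_table(labels["high_pop"], events) == POPULATION_TABLE
        assert build_table(labels["high_prey"], events) == PREY_USE_TABLE
        for (label, expected), mask in zip(
                PREY_BY_POPULATION_STRATA,
                (~labels["high_pop"], labels["high_pop"])):
            got = build_table(labels.loc[mask, "high_prey"],
                              events.loc[mask])
            assert got == expected, label
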