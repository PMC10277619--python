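import numpy as np
import pandas as pd
import pytest

from biodesulf.datasets import FACTOR_SPECS, check_published_values
from biodesulf.exceptions import IncompleteDataError, InvalidDesignError
from biodesulf.orthogonal import (
    FACTORS,
    AnovaSummary,
    DesignTable,
    OrthogonalModel,
    anova,
    build_l16_design,
    range_analysis,
    significance_order,
)
from biodesulf.synthetic import gen_design_responses


class TestL16Construction:
    def test_run_assignments_match_standard_array(self):
        design = build_l16_design(FACTOR_SPECS)
        row5 = design.frame.loc[design.frame["run"] == 5, list(FACTORS)]
        assert row5.values.tolist() == [[2, 2, 3, 4]]
        row1 = design.frame.loc[design.frame["run"] == 1, list(FACTORS)]
        assert row1.values.tolist() == [[1, 1, 1, 1]]

    def test_every_level_appears_four_times_per_factor(self):
        design = build_l16_design(FACTOR_SPECS)
        for f in FACTORS:
            counts = design.frame[f].value_counts()
            assert sorted(counts.index) == [1, 2, 3, 4]
            assert (counts == 4).all()

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(InvalidDesignError):
            build_l16_design(FACTOR_SPECS[:3])

    def test_unbalanced_table_rejected(self):
        frame = build_l16_design(FACTOR_SPECS).frame.copy()
        frame.loc[0, "A"] = 2
        with pytest.raises(InvalidDesignError):
            DesignTable(frame)

    def test_missing_responses_raise_on_analysis(self):
        design = build_l16_design(FACTOR_SPECS)
        with pytest.raises(IncompleteDataError):
            range_analysis(design)


class TestRangeAnalysis:
    def test_study_level_sums_and_superior_levels(self, study_design):
        rs = range_analysis(study_design)
        assert rs.level_sums["A"][0] == pytest.approx(205.13)
        assert rs.level_sums["C"][1] == pytest.approx(255.23)
        assert rs.superior_level == {"A": 3, "B": 4, "C": 2, "D": 3}

    def test_study_display_ranges(self, study_design):
        disp = range_analysis(study_design).rounded(2)
        assert disp.ranges == {"A": 15.63, "B": 9.94, "C": 11.52, "D": 10.07}

    def test_constant_response_gives_zero_ranges(self, study_design):
        design = study_design.with_responses(np.full(16, 50.0))
        rs = range_analysis(design)
        for f in FACTORS:
            assert rs.ranges[f] == pytest.approx(0.0)
            assert rs.level_sums[f] == pytest.approx([200.0] * 4)

    def test_k_sum_conservation(self, study_design):
        rs = range_analysis(study_design)
        for f in FACTORS:
            assert sum(rs.level_sums[f]) == pytest.approx(rs.grand_sum, abs=1e-9)

    def test_minimization_switch(self, study_design):
        rs = range_analysis(study_design, maximize=False)
        assert rs.superior_level["A"] == 1  # lowest mean response at 20 degC


class TestAnova:
    def test_study_sums_of_squares(self, study_design):
        an = anova(study_design)
        ss = an.ss
        assert ss["A"] == pytest.approx(527.40, abs=0.005)
        assert ss["B"] == pytest.approx(208.84, abs=0.005)
        assert ss["D"] == pytest.approx(209.80, abs=0.005)
        assert ss["Error"] == pytest.approx(36.95, abs=0.005)
        # the printed pH sum of squares (365.97) is inconsistent with the
        # run-level responses; the recomputed value is 270.95
        assert ss["C"] == pytest.approx(270.95, abs=0.005)
        assert ss["Total"] == pytest.approx(1253.93, abs=0.005)
        assert an.f_values["A"] == pytest.approx(14.28, abs=0.005)

    def test_decomposition_identity(self, study_design):
        an = anova(study_design).table
        parts = sum(an.loc[f, "sum_sq"] for f in FACTORS) + an.loc["Error", "sum_sq"]
        assert parts == pytest.approx(an.loc["Total", "sum_sq"], abs=1e-9)

    def test_brute_force_oracle_equivalence(self, study_design):
        """SS via K sums equals 4 * sum_i (mean_i - grand mean)^2."""
        y = study_design.responses
        grand_mean = y.mean()
        an = anova(study_design)
        for f in FACTORS:
            levels = study_design.frame[f].to_numpy()
            oracle = 4.0 * sum(
                (y[levels == i].mean() - grand_mean) ** 2 for i in range(1, 5)
            )
            assert an.ss[f] == pytest.approx(oracle, abs=1e-9)

    def test_statsmodels_cross_check(self, study_design):
        """Independent route: categorical OLS ANOVA reproduces the K-sum SS."""
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_api = pytest.importorskip("statsmodels.api")
        frame = study_design.frame.copy()
        for f in FACTORS:
            frame[f] = frame[f].astype("category")
        fit = smf.ols("response ~ A + B + C + D", data=frame).fit()
        table = sm_api.stats.anova_lm(fit, typ=1)
        an = anova(study_design)
        for f in FACTORS:
            assert an.ss[f] == pytest.approx(table.loc[f, "sum_sq"], rel=1e-9)
        assert an.ss["Error"] == pytest.approx(table.loc["Residual", "sum_sq"],
                                               rel=1e-8)

    def test_constant_responses_zero_ss_infinite_f(self, study_design):
        design = study_design.with_responses(np.full(16, 42.0))
        with pytest.warns(UserWarning, match="error mean square is zero"):
            an = anova(design)
        assert all(an.ss[f] == pytest.approx(0.0, abs=1e-9) for f in FACTORS)
        assert np.isinf(an.f_values).all()
        assert (an.table.loc[list(FACTORS), "p"] == 0.0).all()

    def test_p_values_in_unit_interval(self, study_design):
        an = anova(study_design)
        p = an.table.loc[list(FACTORS), "p"]
        assert ((p >= 0) & (p <= 1)).all()


class TestSignificanceOrder:
    def test_study_order(self, study_design):
        res = OrthogonalModel(study_design).fit()
        assert res.significance_order == ["A", "C", "D", "B"]

    def test_explicit_f_sorting_and_ties(self):
        def make(fvals):
            table = pd.DataFrame(
                {"df": 3, "sum_sq": 1.0, "mean_sq": 1.0,
                 "F": fvals + [np.nan, np.nan], "p": 0.5},
                index=list(FACTORS) + ["Error", "Total"],
            )
            table.index.name = "source"
            return AnovaSummary(table)

        assert significance_order(make([1.0, 2.0, 3.0, 4.0])) == ["D", "C", "B", "A"]
        with pytest.warns(UserWarning, match="tied"):
            assert significance_order(make([2.0, 2.0, 2.0, 2.0])) == ["A", "B", "C", "D"]


class TestInvariancesAndDetection:
    def test_run_permutation_leaves_results_unchanged(self, study_design):
        base = OrthogonalModel(study_design).fit()
        rng = np.random.default_rng(0)
        frame = study_design.frame.sample(frac=1.0, random_state=rng.integers(2**31))
        permuted = OrthogonalModel(DesignTable(frame)).fit()
        for f in FACTORS:
            assert permuted.range_summary.level_sums[f] == pytest.approx(
                base.range_summary.level_sums[f]
            )
        pd.testing.assert_frame_equal(permuted.anova_summary.table,
                                      base.anova_summary.table)

    def test_injected_effect_detected_as_largest_f(self):
        effects = {f: [0.0, 0.0, 0.0, 0.0] for f in FACTORS}
        effects["C"] = [-6.0, -2.0, 2.0, 6.0]
        design = gen_design_responses(effects, grand_mean=55.0, noise_sd=0.5, seed=11)
        an = anova(design)
        assert an.f_values.idxmax() == "C"

    def test_published_cross_check_flags_known_typos(self, study_design):
        issues = check_published_values(OrthogonalModel(study_design).fit())
        text = " ".join(issues)
        assert "K_4D" in text
        assert "squares C" in text
        assert "Total" in text
        # everything else reconciles
        assert not any(k in text for k in ("K_1A", "squares A", "F_A", "R_"))
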