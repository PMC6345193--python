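"""Trajectory inference: design building, OLS, term tests, classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_wide_participants, normal_equations
from spantraj.cohort import MBID, TD
from spantraj.effects import add_effect_scores
from spantraj.exceptions import (
    GroupingError,
    SchemaError,
    SingularDesignError,
    UsageError,
)
from spantraj.pipeline import PipelineConfig, scenario_config
from spantraj.cohort import simulate_cohort
from spantraj.trajectories import (
    DevelopmentalTrajectory,
    ModelSpec,
    PatternClassification,
    build_design,
    classify_pattern,
    fit_ols,
    per_group_slope_test,
    rescale_di,
    sensitivity_refit,
    single_term_tests,
    term_test,
)

COEF_RTOL = 1e-8   # coefficient agreement tolerance
P_ATOL = 1e-6      # p-value agreement tolerance


class TestRescaleDI:
    def test_subtracts_the_mbid_minimum(self):
        vals = [88, 100, 72, 95]
        groups = [MBID, MBID, TD, TD]
        out = rescale_di(vals, groups)
        assert list(out) == [0, 12, -16, 7]

    def test_constant_values_map_to_zero(self):
        assert np.all(rescale_di([5, 5, 5], [MBID, MBID, TD]) == 0)

    def test_requires_mbid_participants(self):
        with pytest.raises(GroupingError):
            rescale_di([1, 2], [TD, TD])


class TestBuildDesign:
    @staticmethod
    def _data(n=12, task=True):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({
            "di": rng.uniform(0, 50, n),
            "group_mbid": (np.arange(n) % 2).astype(float),
        })
        if task:
            d["task_c"] = np.where(np.arange(n) < n // 2, 0.5, -0.5)
        return d

    def test_step_one_has_two_columns(self):
        X = build_design(self._data(), ModelSpec("capacity", "CA", step=1))
        assert list(X.columns) == ["const", "DI"]

    def test_step_four_rehearsal_has_eight_named_columns(self):
        X = build_design(self._data(), ModelSpec("rehearsal", "CA", step=4))
        assert list(X.columns) == [
            "const", "DI", "Group", "Group:DI", "Length", "Length:DI",
            "Length:Group", "Length:Group:DI",
        ]

    def test_column_count_strictly_increases_with_step(self):
        widths = [
            build_design(self._data(), ModelSpec("redintegration", "VOC", step=s)).shape[1]
            for s in range(1, 5)
        ]
        assert widths == sorted(set(widths)) == [2, 4, 6, 8]

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(SchemaError):
            build_design(self._data(task=False), ModelSpec("rehearsal", "CA", step=3))

    def test_capacity_has_no_task_steps(self):
        with pytest.raises(UsageError):
            ModelSpec("capacity", "CA", step=3)


class TestFitOLS:
    def test_exact_linear_data_interpolated(self):
        X = pd.DataFrame({"const": np.ones(10), "DI": np.arange(10.0)})
        y = 1.5 + 0.25 * X["DI"]
        fit = fit_ols(X, y)
        assert fit.params["DI"] == pytest.approx(0.25, rel=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({
            "const": np.ones(6),
            "DI": rng.uniform(0, 10, 6),
            "Group": [0, 1, 0, 1, 0, 1.0],
        })
        y = rng.normal(size=6)
        fit = fit_ols(X, y)
        expected = normal_equations(X, y)
        assert np.allclose(fit.params.to_numpy(), expected, atol=1e-10)

    def test_column_orthogonal_to_design_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"const": np.ones(20), "DI": rng.uniform(0, 1, 20)})
        y = rng.normal(size=20)
        z = rng.normal(size=20)
        A = np.column_stack([X["const"], X["DI"]])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]  # project out
        base = fit_ols(X, y)
        aug = fit_ols(X.assign(extra=z), y)
        assert np.allclose(aug.params[["const", "DI"]], base.params, rtol=COEF_RTOL)

    def test_singular_design_names_collinear_terms(self):
        # DI constant within the MBID group makes Group:DI a multiple of Group
        X = pd.DataFrame({
            "const": np.ones(8),
            "DI": [3, 3, 3, 3, 1, 2, 4, 5.0],
            "Group": [1, 1, 1, 1, 0, 0, 0, 0.0],
        })
        X["Group:DI"] = X["Group"] * X["DI"]
        with pytest.raises(SingularDesignError, match="Group"):
            fit_ols(X, np.arange(8.0))

    def test_underdetermined_fit_rejected(self):
        X = pd.DataFrame({"const": np.ones(2), "DI": [1.0, 2.0]})
        with pytest.raises(UsageError):
            fit_ols(X, [1.0, 2.0])


class TestTermTest:
    @staticmethod
    def _toy_fit(n=30, seed=0, with_interaction=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "const": np.ones(n),
            "DI": rng.uniform(0, 30, n),
            "Group": (np.arange(n) % 2).astype(float),
        })
        if with_interaction:
            X["Group:DI"] = X["Group"] * X["DI"]
        y = rng.normal(size=n)
        return X, y

    def test_identical_rss_gives_f_zero_p_one(self):
        X, y = self._toy_fit()
        A = np.column_stack([X["const"], X["DI"], X["Group"]])
        z = np.random.default_rng(1).normal(size=len(y))
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
        y_fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        resid = y - y_fit
        resid = resid - z * (resid @ z) / (z @ z)  # kill the extra column too
        y2 = y_fit + resid
        small = fit_ols(X[["const", "DI", "Group"]], y2)
        big = fit_ols(X[["const", "DI", "Group"]].assign(extra=z), y2)
        tt = term_test(big, small)
        assert tt.F == pytest.approx(0.0, abs=1e-9)
        assert tt.p == pytest.approx(1.0, abs=1e-6)

    def test_single_df_partial_f_equals_squared_t(self):
        X, y = self._toy_fit(seed=5)
        fit = fit_ols(X, y)
        for term, tt in single_term_tests(fit).items():
            t = fit.params[term] / fit.bse[term]
            assert tt.F == pytest.approx(t**2, rel=1e-10)

    def test_non_nested_models_rejected(self):
        X, y = self._toy_fit()
        f1 = fit_ols(X[["const", "DI"]], y)
        f2 = fit_ols(X[["const", "Group"]], y)
        with pytest.raises(UsageError):
            term_test(f1, f2)

    def test_parametric_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        n = 30
        X, _ = self._toy_fit(n=n, seed=12)
        y = rng.normal(size=n)
        full = fit_ols(X, y)
        tt = single_term_tests(full)["Group:DI"]
        A_f = X.to_numpy()
        A_r = X.drop(columns=["Group:DI"]).to_numpy()
        M_f = np.eye(n) - A_f @ np.linalg.pinv(A_f)
        M_r = np.eye(n) - A_r @ np.linalg.pinv(A_r)
        df_den = n - A_f.shape[1]
        perms = np.array([rng.permutation(y) for _ in range(2000)])
        rss_f = np.einsum("ij,jk,ik->i", perms, M_f, perms)
        rss_r = np.einsum("ij,jk,ik->i", perms, M_r, perms)
        F_perm = (rss_r - rss_f) / (rss_f / df_den)
        p_perm = float(np.mean(F_perm >= tt.F))
        assert tt.p == pytest.approx(p_perm, abs=0.03)


class TestClassification:
    def test_label_taxonomy_is_unique_function_of_flags(self):
        assert PatternClassification._label(True, False) == "delayed_onset"
        assert PatternClassification._label(False, True) == "slowed_rate"
        assert PatternClassification._label(True, True) == "combination"
        assert PatternClassification._label(False, False) == "no_difference"

    @pytest.mark.parametrize("scenario,expected", [
        ("onset", "delayed_onset"),
        ("rate", "slowed_rate"),
        ("null", "no_difference"),
    ])
    def test_generated_scenarios_recovered(self, scenario, expected):
        cc = scenario_config(PipelineConfig(), scenario, seed=2024)
        parts = simulate_cohort(cc, return_trials=False)
        res = DevelopmentalTrajectory(parts, outcome="capacity", di="CA").fit()
        assert res.classification.label == expected

    def test_requires_final_step_terms(self):
        parts = simulate_cohort(PipelineConfig().cohort, return_trials=False)
        model = DevelopmentalTrajectory(parts, outcome="rehearsal", di="CA")
        res = model.fit(step=2)
        with pytest.raises(UsageError):
            classify_pattern(res.final_fit, model.spec)


class TestEquivalences:
    def test_step2_saturated_fit_equals_per_group_regressions(self, participants):
        res = DevelopmentalTrajectory(participants, outcome="capacity", di="CA").fit()
        fit = res.step_fits[2]
        data = res.model.data
        for group, mask in ((TD, data["group_mbid"] == 0),
                            (MBID, data["group_mbid"] == 1)):
            sub = data[mask]
            A = np.column_stack([np.ones(len(sub)), sub["di"]])
            b = normal_equations(A, sub["y"])
            if group == TD:
                est = (fit.params["const"], fit.params["DI"])
            else:
                est = (fit.params["const"] + fit.params["Group"],
                       fit.params["DI"] + fit.params["Group:DI"])
            assert np.allclose(est, b, rtol=COEF_RTOL)

    def test_full_interaction_slopes_equal_separate_difference_fits(self, participants):
        res = DevelopmentalTrajectory(participants, outcome="rehearsal", di="CA").fit()
        fit = res.final_fit
        spec = ModelSpec("rehearsal", "CA")
        _, _, slope_td, _ = per_group_slope_test(participants, TD, spec)
        _, _, slope_mbid, _ = per_group_slope_test(participants, MBID, spec)
        assert fit.params["Length:DI"] == pytest.approx(slope_td, rel=COEF_RTOL)
        assert fit.params["Length:DI"] + fit.params["Length:Group:DI"] == pytest.approx(
            slope_mbid, rel=COEF_RTOL
        )

    def test_shift_invariance_of_slope_statistics(self, participants):
        """Any affine shift of the DI column is absorbed by the rescaling:
        all slope and interaction F statistics are unchanged."""
        shifted = participants.copy()
        shifted["ca_months"] = shifted["ca_months"] + 37.5
        for outcome in ("capacity", "rehearsal"):
            a = DevelopmentalTrajectory(participants, outcome=outcome, di="CA").fit()
            b = DevelopmentalTrajectory(shifted, outcome=outcome, di="CA").fit()
            for s in a.step_tests:
                for term, tt in a.step_tests[s].items():
                    tt2 = b.step_tests[s][term]
                    assert tt2.F == pytest.approx(tt.F, rel=COEF_RTOL)
                    assert tt2.p == pytest.approx(tt.p, abs=P_ATOL)
            assert a.classification.label == b.classification.label

    def test_cluster_robust_changes_only_standard_errors(self, participants):
        plain = DevelopmentalTrajectory(participants, outcome="rehearsal", di="CA").fit()
        robust = DevelopmentalTrajectory(participants, outcome="rehearsal", di="CA",
                                         cluster_robust=True).fit()
        assert np.allclose(plain.params, robust.params, rtol=1e-12)
        assert not np.allclose(plain.bse, robust.bse)


class TestPerGroupSlopeTest:
    def test_deterministic_linear_data_has_tiny_p(self):
        n = 40
        di = np.linspace(90, 200, n)
        y = 1.0 + 0.02 * di + np.random.default_rng(0).normal(0, 1e-3, n)
        parts = make_wide_participants(
            [f"m{i}" for i in range(n)], [MBID] * n, di, y
        )
        F, p, slope, df = per_group_slope_test(parts, MBID, ModelSpec("capacity", "CA"))
        assert p < 1e-10
        assert slope == pytest.approx(0.02, rel=1e-3)
        assert df == n - 2

    def test_too_small_group_rejected(self):
        parts = make_wide_participants(["a", "b"], [MBID, MBID], [1, 2], [3.0, 3.1])
        with pytest.raises(UsageError):
            per_group_slope_test(parts, MBID, ModelSpec("capacity", "CA"))


class TestSensitivity:
    def test_empty_exclusion_is_identity(self, participants):
        spec = ModelSpec("capacity", "CA")
        sens = sensitivity_refit(participants, [], spec)
        assert sens.n_excluded == 0
        a, b = sens.before.final_fit, sens.after.final_fit
        assert np.allclose(a.params, b.params, rtol=1e-12)
        assert not sens.flips()

    def test_predicate_excludes_matching_count(self, participants):
        spec = ModelSpec("capacity", "COG")
        rule = lambda d: d["cog_raw"].fillna(np.inf) < 45  # noqa: E731
        sens = sensitivity_refit(participants, rule, spec)
        assert sens.n_excluded == int((participants["cog_raw"] < 45).sum())

    def test_high_leverage_point_flips_marginal_slope_term(self):
        rng = np.random.default_rng(8)
        n = 20
        di = np.concatenate([np.linspace(0, 19, n), np.linspace(0, 19, n)])
        groups = [MBID] * n + [TD] * n
        ids = [f"p{i}" for i in range(2 * n)]
        y = 2.0 + 0.05 * di + rng.normal(0, 0.1, 2 * n)
        parts = make_wide_participants(ids, groups, di, y)
        outlier = make_wide_participants(["lev"], [MBID], [60.0], [2.0 + 0.05 * 60 + 3.0])
        full = pd.concat([parts, outlier], ignore_index=True)
        sens = sensitivity_refit(full, ["lev"], ModelSpec("capacity", "CA"))
        before = sens.before.step_tests[2]["Group:DI"].p
        after = sens.after.step_tests[2]["Group:DI"].p
        assert before < 0.05 <= after
        assert sens.flips()["Group:DI"] == (True, False)

    def test_emptying_a_group_raises(self, participants):
        mbid_ids = participants.loc[participants["group"] == MBID, "participant_id"]
        with pytest.raises(GroupingError):
            sensitivity_refit(participants, list(mbid_ids), ModelSpec("capacity", "CA"))


def test_results_reporting_surfaces(participants):
    res = DevelopmentalTrajectory(participants, outcome="redintegration", di="VOC").fit()
    text = res.summary()
    assert "redintegration ~ VOC" in text and "Lexicality:Group:DI" in text
    d = res.to_dict()
    assert set(d["steps"]) == {"1", "2", "3", "4"}
    assert d["classification"]["label"] == res.classification.label
    table = res.fitted_effect_table()
    assert {"participant_id", "group", "observed_effect", "fitted_effect"} <= set(table.columns)
    scored = add_effect_scores(participants).set_index("participant_id")
    merged = table.set_index("participant_id")
    common = merged.index.intersection(scored.index)
    assert np.allclose(merged.loc[common, "observed_effect"],
                       scored.loc[common, "redintegration_effect"])
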