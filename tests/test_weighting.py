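"""Screening, imputation, propensity weighting, combination, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelreact import weighting as wt
from panelreact.errors import EstimationError, SchemaError, ValidationError

from conftest import make_selection_frame


class TestScreening:
    def test_threshold_rule(self):
        frame = pd.DataFrame(
            {
                "ok": [1.0] * 96 + [np.nan] * 4,
                "bad": [1.0] * 90 + [np.nan] * 10,
            }
        )
        admitted, rejected = wt.screen_missingness(frame, ["ok", "bad"])
        assert admitted == ["ok"]
        assert rejected["bad"] == pytest.approx(0.10)

    def test_ten_row_fixture(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6, 7, 8, 9, np.nan]})
        _, rejected = wt.screen_missingness(frame, ["x"], threshold=0.05)
        assert rejected["x"] == pytest.approx(0.10)

    def test_zero_threshold_admits_only_complete(self):
        frame = pd.DataFrame({"full": [1.0, 2.0], "gap": [1.0, np.nan]})
        admitted, _ = wt.screen_missingness(frame, ["full", "gap"], threshold=0.0)
        assert admitted == ["full"]

    def test_structural_missings_not_counted(self):
        frame = pd.DataFrame({"scale": [np.nan] * 50 + [1.0] * 50, "age_w2": [8] * 50 + [14] * 50})
        structural = {"scale": frame["age_w2"] < 11}
        admitted, _ = wt.screen_missingness(frame, ["scale"], structural=structural)
        assert admitted == ["scale"]


class TestImputation:
    def test_lower_median_for_even_count(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0]})
        out, log = wt.impute_simple(frame, ["x"])
        assert out.loc[2, "x"] == 2.0
        assert log == {"x": 1}

    def test_mode_for_categorical(self):
        frame = pd.DataFrame({"c": ["a", "a", "b", np.nan]})
        out, _ = wt.impute_simple(frame, ["c"], categorical=["c"])
        assert out.loc[3, "c"] == "a"

    def test_mode_tie_broken_by_level_order(self):
        frame = pd.DataFrame({"c": ["b", "b", "a", "a", np.nan]})
        out, _ = wt.impute_simple(
            frame, ["c"], categorical=["c"], level_order={"c": ["b", "a"]}
        )
        assert out.loc[4, "c"] == "b"

    def test_no_missing_is_identity(self):
        frame = pd.DataFrame({"x": [1.0, 2.0]})
        out, log = wt.impute_simple(frame, ["x"])
        pd.testing.assert_frame_equal(frame, out)
        assert log == {}

    def test_fully_missing_rejected(self):
        frame = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(EstimationError):
            wt.impute_simple(frame, ["x"])


class TestMergeUserMissing:
    def _frame(self, um_rate_num, um_rate_den):
        rows = []
        rows += [("A", 1)] * 30 + [("A", 0)] * 70  # rate 0.30
        rows += [("B", 1)] * 50 + [("B", 0)] * 50  # rate 0.50
        rows += [("user_missing", 1)] * um_rate_num + [("user_missing", 0)] * (
            um_rate_den - um_rate_num
        )
        return pd.DataFrame(rows, columns=["v", "y"])

    def test_merged_into_nearest_rate(self):
        out, log = wt.merge_user_missing(self._frame(33, 100), "v", "y")
        assert log["merged_into"] == "A"
        assert not (out["v"] == "user_missing").any()

    def test_midway_tie_goes_to_larger_level(self):
        rows = [("A", 1)] * 3 + [("A", 0)] * 7  # rate 0.30, n=10
        rows += [("B", 1)] * 10 + [("B", 0)] * 10  # rate 0.50, n=20
        rows += [("user_missing", 1)] * 4 + [("user_missing", 0)] * 6  # rate 0.40
        out, log = wt.merge_user_missing(pd.DataFrame(rows, columns=["v", "y"]), "v", "y")
        assert log["merged_into"] == "B"

    def test_no_user_missing_rows_noop(self):
        frame = pd.DataFrame({"v": ["A", "B"], "y": [0, 1]})
        out, log = wt.merge_user_missing(frame, "v", "y")
        assert log["action"].startswith("no user-missing")
        pd.testing.assert_frame_equal(frame, out)


class TestPropensity:
    def test_intercept_only_equal_weights(self):
        frame = pd.DataFrame({"y": [1] * 40 + [0] * 60})
        spec = wt.PropensitySpec(outcome="y", main_effects=[])
        theta, _ = wt.estimate_propensity(frame, spec, np.ones(100))
        assert np.allclose(theta, 0.40, atol=1e-8)

    def test_intercept_only_weighted_closed_form(self):
        frame = pd.DataFrame({"y": [1, 1, 0, 0]})
        w = np.array([2.0, 1.0, 1.0, 1.0])
        spec = wt.PropensitySpec(outcome="y", main_effects=[])
        theta, _ = wt.estimate_propensity(frame, spec, w)
        assert np.allclose(theta, 3.0 / 5.0, atol=1e-8)

    def test_floor_applied_and_logged(self):
        frame = pd.DataFrame({"y": [1] + [0] * 999})
        spec = wt.PropensitySpec(outcome="y", main_effects=[])
        theta, log = wt.estimate_propensity(frame, spec, np.ones(1000), floor=0.01)
        assert (theta >= 0.01).all()
        assert log["n_floored"] == 1000


class TestComputeWeights:
    def test_theta_one_is_identity(self):
        theta = pd.Series([1.0, 1.0])
        base = pd.Series([2.0, 3.0])
        out = wt.compute_weights(theta, base, "registered")
        assert np.allclose(out["wls"], base)

    def test_direct_formula(self):
        out = wt.compute_weights(pd.Series([0.4]), pd.Series([2.0]), "registered")
        assert out["wls"].iloc[0] == pytest.approx(5.0)

    def test_horvitz_thompson_total_recovery(self):
        # intercept-only propensity, equal base weights: weighted respondent
        # count equals the full-frame count
        frame = pd.DataFrame({"y": [1] * 37 + [0] * 63})
        spec = wt.PropensitySpec(outcome="y", main_effects=[])
        theta, _ = wt.estimate_propensity(frame, spec, np.ones(100))
        out = wt.compute_weights(theta, pd.Series(np.ones(100)), "y", frame["y"] == 1)
        assert out["wls"].sum() == pytest.approx(100.0, rel=1e-6)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValidationError):
            wt.compute_weights(pd.Series([0.0]), pd.Series([1.0]), "s")
        with pytest.raises(ValidationError):
            wt.compute_weights(pd.Series([1.5]), pd.Series([1.0]), "s")

    def test_chaining_consistency(self):
        rng = np.random.default_rng(0)
        base = pd.Series(rng.uniform(0.5, 2.0, 500))
        theta_reg = pd.Series(rng.uniform(0.1, 0.9, 500))
        theta_part = pd.Series(rng.uniform(0.1, 0.9, 500))
        chained = wt.compute_weights(
            theta_part, wt.compute_weights(theta_reg, base, "reg")["wls"], "part"
        )["wls"]
        single = base / (theta_reg * theta_part)
        assert np.allclose(chained, single, rtol=1e-10)


class TestCombineSubsamples:
    def _ws(self, weights, offset=0):
        w = pd.Series(weights, index=range(offset, offset + len(weights)), dtype=float)
        return pd.DataFrame({"theta": 1.0, "base_weight": 1.0, "wls": w, "stage": "reg"})

    def test_symmetric_subsamples(self):
        a = self._ws([1.0, 2.0, 3.0])
        b = self._ws([1.0, 2.0, 3.0], offset=10)
        combined, lam = wt.combine_subsamples(a, b)
        assert lam["a"] == pytest.approx(0.5)
        ratios = combined["wls_combined"] / combined["wls"]
        assert np.allclose(ratios, ratios.iloc[0])

    def test_hand_kish_arithmetic(self):
        a = self._ws([1.0] * 100)
        b = self._ws([3.0] + [1.0] * 99, offset=200)
        _, lam = wt.combine_subsamples(a, b)
        neff_b = 102.0**2 / 108.0
        assert lam["a"] == pytest.approx(100.0 / (100.0 + neff_b))
        assert lam["b"] == pytest.approx(neff_b / (100.0 + neff_b))

    def test_effective_allocation_beats_nominal(self):
        a = self._ws([1.0] * 200)
        rng = np.random.default_rng(1)
        b = self._ws(np.exp(rng.normal(0, 1.2, 200)), offset=500)

        def combined_eff(lam_a):
            wa = a["wls"] * (lam_a / a["wls"].sum())
            wb = b["wls"] * ((1 - lam_a) / b["wls"].sum())
            w = np.concatenate([wa, wb])
            return wt.kish_n_eff(w) / len(w)

        neff = {"a": wt.kish_n_eff(a["wls"]), "b": wt.kish_n_eff(b["wls"])}
        lam_eff = neff["a"] / (neff["a"] + neff["b"])
        assert combined_eff(lam_eff) >= combined_eff(0.5)  # nominal-n allocation

    def test_order_preserved_within_subsample(self):
        rng = np.random.default_rng(2)
        a = self._ws(rng.uniform(0.2, 3.0, 50))
        b = self._ws(rng.uniform(0.2, 3.0, 80), offset=100)
        combined, _ = wt.combine_subsamples(a, b)
        for ws in (a, b):
            sub = combined.loc[ws.index]
            assert (sub["wls_combined"].argsort().to_numpy() == sub["wls"].argsort().to_numpy()).all()

    def test_empty_subsample_passthrough(self):
        a = self._ws([])
        b = self._ws([2.0, 4.0], offset=10)
        with pytest.warns(UserWarning):
            combined, lam = wt.combine_subsamples(a, b)
        assert lam["b"] == 1.0
        assert combined["wls_combined"].mean() == pytest.approx(1.0)


class TestDiagnostics:
    def test_all_unit_weights(self):
        d = wt.weight_diagnostics(np.ones(50))
        assert (d.minimum, d.median, d.maximum) == (1.0, 1.0, 1.0)
        assert d.cv == 0.0
        assert d.effectiveness == 100.0

    def test_brute_force_kish(self):
        d = wt.weight_diagnostics([2.0, 1.0, 1.0])
        assert d.n_eff == pytest.approx(16.0 / 6.0)
        assert d.effectiveness == pytest.approx(100 * (16.0 / 6.0) / 3)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100.0, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_effectiveness_cv_identity(self, weights):
        d = wt.weight_diagnostics(np.array(weights))
        assert d.effectiveness == pytest.approx(100.0 / (1.0 + (d.cv / 100.0) ** 2), abs=1e-9)
        assert d.minimum <= d.median <= d.maximum
        assert 0 < d.effectiveness <= 100 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            wt.weight_diagnostics(np.array([]))


class TestBalanceReport:
    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame({"sex": rng.choice(["male", "female"], 500)})
        resp = base.iloc[:200]
        report = wt.balance_report(base, resp, np.ones(200), ["sex"])
        t = report.table
        assert np.allclose(t["weighted_pct"], t["unweighted_pct"])

    def test_two_level_closure(self):
        rng = np.random.default_rng(4)
        base = pd.DataFrame({"sex": rng.choice(["male", "female"], 300)})
        report = wt.balance_report(base, base, rng.uniform(0.5, 2, 300), ["sex"])
        for col in ("reference_pct", "unweighted_pct", "weighted_pct"):
            assert report.table[col].sum() == pytest.approx(100.0, abs=0.05)

    def test_missing_parameter_rejected(self):
        base = pd.DataFrame({"sex": ["male"]})
        with pytest.raises(SchemaError):
            wt.balance_report(base, base, np.ones(1), ["ghost"])


class TestStepwiseUnits:
    def test_true_predictor_selected_single_run(self):
        frame = make_selection_frame(0, np.log(2.5))
        spec = wt.stepwise_select(
            frame, "y", np.ones(len(frame)),
            ["x_true", "noise0", "noise1", "noise2", "noise3", "noise4"],
            categorical={"sex": "male"}, interaction_partners=("age_w2", "sex"),
        )
        assert "x_true" in spec.main_effects

    def test_deterministic_predictor_pruned_to_intercept(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        frame = pd.DataFrame({"y": y, "copy": y.astype(float)})
        with pytest.warns(UserWarning, match="intercept-only"):
            spec = wt.stepwise_select(
                frame, "y", np.ones(400), ["copy"], interaction_partners=()
            )
        assert spec.main_effects == []
        theta, _ = wt.estimate_propensity(frame, spec, np.ones(400))
        assert np.allclose(theta, y.mean(), atol=1e-8)

    def test_interaction_parents_in_model(self):
        frame = make_selection_frame(5, np.log(3.0))
        frame["x_true:age"] = 0.0  # unused; ensures no name clash trouble
        spec = wt.stepwise_select(
            frame, "y", np.ones(len(frame)),
            ["x_true", "noise0"], categorical={"sex": "male"},
            interaction_partners=("age_w2", "sex"),
        )
        for a, b in spec.interactions:
            assert a in spec.main_effects and b in spec.main_effects
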