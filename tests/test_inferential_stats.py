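import numpy as np
import pandas as pd
import pytest

from karstdiv.community_model import ValidationError
from karstdiv.inferential_stats import (
    normality_gate,
    pearson_matrix,
    stage_anova,
    stepwise_regression,
)


def records(values_by_stage, metric="SD"):
    rows = []
    for stage, vals in values_by_stage.items():
        for v in vals:
            rows.append({"stage": stage, metric: v})
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_identical_values_reported_degenerate_fail(self):
        vals = np.array([1.0] * 5 + [1.0, 2.0, 3.0, 2.5, 1.5])
        grp = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="normality gate failed"):
            rep = normality_gate(vals, grp, metric="SD")
        row = rep.table.set_index("group").loc["a"]
        assert not rep.passed and row["degenerate"] and not row["normal"]

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="n = 2"):
            normality_gate(np.arange(5.0), np.array(["a", "a", "b", "b", "b"]))

    def test_gaussian_passes_lognormal_fails_across_seeds(self):
        n_pass = n_fail = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            gauss = rng.normal(size=50)
            logn = rng.lognormal(mean=0.0, sigma=1.5, size=50)
            grp = np.array(["g"] * 50)
            if normality_gate(gauss, grp).passed:
                n_pass += 1
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if not normality_gate(logn, grp).passed:
                    n_fail += 1
        assert n_pass >= 90
        assert n_fail >= 90

    def test_hard_gate_raises(self):
        vals = np.concatenate([np.ones(3), [1.0, 2.0, 3.0]])
        grp = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValidationError, match="normality gate failed"):
            normality_gate(vals, grp, hard=True)


class TestStageAnova:
    def test_all_equal_shares_one_letter(self):
        df = records({s: [2.0, 2.0, 2.0] for s in ("HE", "HS", "SH", "TS", "TR")})
        res = stage_anova(df, "SD")
        assert res.F == 0.0 and res.p == 1.0
        assert set(res.letters.values()) == {"a"}

    @pytest.mark.parametrize("method", ["tukey", "lsd"])
    def test_well_separated_groups_get_distinct_letters(self, method):
        rng = np.random.default_rng(5)
        df = records(
            {
                s: (m + rng.normal(0, 0.01, 3)).tolist()
                for s, m in zip(("HE", "HS", "SH", "TS", "TR"), (1, 2, 3, 4, 5))
            }
        )
        res = stage_anova(df, "SD", method=method)
        letters = [res.letters[s] for s in ("TR", "TS", "SH", "HS", "HE")]
        assert letters == ["a", "b", "c", "d", "e"]
        assert res.p < 1e-6

    def test_two_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(7)
        base = {"HE": 1.0, "HS": 1.0, "SH": 5.0, "TS": 9.0, "TR": 13.0}
        df = records({s: (m + rng.normal(0, 0.05, 3)).tolist() for s, m in base.items()})
        res = stage_anova(df, "SD")
        assert set(res.letters["HE"]) & set(res.letters["HS"])

    def test_letter_sharing_mirrors_tukey_significance(self):
        """Two groups share a letter iff Tukey finds them not different."""
        for seed in range(12):
            rng = np.random.default_rng(seed)
            df = records(
                {
                    s: (m + rng.normal(0, 0.8, 3)).tolist()
                    for s, m in zip(("HE", "HS", "SH", "TS", "TR"), (1, 1.5, 2, 4, 8))
                }
            )
            res = stage_anova(df, "SD")
            for (g1, g2), p in res.pairwise_p.items():
                shared = bool(set(res.letters[g1]) & set(res.letters[g2]))
                assert shared == (p >= 0.05), (seed, g1, g2, p, res.letters)

    def test_singleton_group_rejected(self):
        df = records({"HE": [1.0], "HS": [1.0, 2.0, 1.5]})
        with pytest.raises(ValidationError, match="n = 1"):
            stage_anova(df, "SD")


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        res = pearson_matrix(df)
        assert res.r.loc["x", "up"] == pytest.approx(1.0)
        assert res.r.loc["x", "down"] == pytest.approx(-1.0)
        assert (np.diag(res.r) == 1).all()

    def test_zero_correlation_three_points(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 0.0]})
        res = pearson_matrix(df)
        assert res.r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_covariance_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pearson_matrix(df)
        for c1 in "abcd":
            for c2 in "abcd":
                x, y = df[c1].to_numpy(), df[c2].to_numpy()
                r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert res.r.loc[c1, c2] == pytest.approx(r, abs=1e-12)

    def test_star_thresholds(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "strong": x + rng.normal(0, 0.1, n)})
        res = pearson_matrix(df)
        assert res.stars.loc["x", "strong"] == "***"

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValidationError, match="flat"):
            pearson_matrix(df)


class TestStepwise:
    def test_pure_signal_keeps_only_x1(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        y = 2.0 * x1
        res = stepwise_regression(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.included == ["x1"]
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_signals_retained_with_similar_standardized_weights(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        y = x1 + x2 + rng.normal(0, 0.01, 50)
        res = stepwise_regression(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert sorted(res.included) == ["x1", "x2"]
        b1, b2 = res.std_coefficients["x1"], res.std_coefficients["x2"]
        assert abs(b1 - b2) < 0.05

    def test_pure_noise_yields_empty_model(self):
        empty = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=50)
            X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x1", "x2"])
            res = stepwise_regression(y, X)
            if res.included == []:
                assert res.r_squared == 0.0
                empty += 1
        assert empty >= 45  # >= 90% of seeds

    def test_standardized_coefficient_identity(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"x1": rng.normal(0, 3, 60), "x2": rng.uniform(0, 10, 60)}
        )
        y = 0.5 * X["x1"] - 0.2 * X["x2"] + rng.normal(0, 0.5, 60)
        res = stepwise_regression(y.to_numpy(), X)
        sy = np.std(y, ddof=1)
        for c in res.included:
            expected = res.coefficients[c] * np.std(X[c], ddof=1) / sy
            assert res.std_coefficients[c] == pytest.approx(expected, abs=1e-10)

    def test_forced_entry_reproduces_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["x1", "x2"])
        y = 1.0 + 0.3 * X["x1"] + rng.normal(0, 1.0, 40)
        res = stepwise_regression(y.to_numpy(), X, entry_p=1.0, stay_p=1.0)
        full = sm.OLS(y.to_numpy(), sm.add_constant(X)).fit()
        assert sorted(res.included) == ["x1", "x2"]
        assert res.intercept == pytest.approx(full.params["const"], abs=1e-10)
        for c in ("x1", "x2"):
            assert res.coefficients[c] == pytest.approx(full.params[c], abs=1e-10)
        assert res.r_squared == pytest.approx(full.rsquared, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValidationError, match="collinear"):
            stepwise_regression(x, X)
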