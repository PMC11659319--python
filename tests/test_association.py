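"""Regression suite: fits, diagnostics, invariants, group comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from abrcog.association import (
    RegressionSpec,
    compare_age_groups,
    fit_linear_model,
    model_diagnostics,
    run_association_suite,
)
from abrcog.schema import InputError, ModelError


def df_from(**cols):
    return pd.DataFrame(cols)


class TestFitLinearModel:
    def test_perfect_fit_slope_one_and_collapsed_ci(self):
        x = np.arange(20, dtype=float)
        res = fit_linear_model(df_from(y=x.copy(), x=x), RegressionSpec("y", "x"))
        assert res.B == pytest.approx(1.0, abs=1e-12)
        assert res.ci95[1] - res.ci95[0] == pytest.approx(0.0, abs=1e-9)

    def test_outcome_equals_predictor_rejected(self):
        with pytest.raises(InputError):
            RegressionSpec("y", "y")

    def test_insufficient_n_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ModelError, match="observations-per-IV"):
            fit_linear_model(df_from(y=x, x=x + 1), RegressionSpec("y", "x"))

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ModelError, match="rank"):
            fit_linear_model(
                df_from(y=rng.normal(size=30), x=x, x2=2 * x),
                RegressionSpec("y", "x", covariates=("x2",)),
            )

    def test_zscored_slope_equals_pearson_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        res = fit_linear_model(
            df_from(y=y, x=x), RegressionSpec("y", "x", standardize=("y", "x"))
        )
        r = np.corrcoef(x, y)[0, 1]
        assert res.B == pytest.approx(r, abs=1e-10)

    def test_frisch_waugh_equivalence(self, rng):
        n = 150
        age = rng.uniform(18, 92, n)
        pred = 0.01 * age + rng.normal(size=n)
        y = -0.02 * age + 0.3 * pred + rng.normal(size=n)
        table = df_from(y=y, pred=pred, age=age)
        res = fit_linear_model(table, RegressionSpec("y", "pred", covariates=("age",)))
        X_age = sm.add_constant(age)
        ry = y - X_age @ np.linalg.lstsq(X_age, y, rcond=None)[0]
        rp = pred - X_age @ np.linalg.lstsq(X_age, pred, rcond=None)[0]
        slope = float(rp @ ry / (rp @ rp))
        assert res.B == pytest.approx(slope, abs=1e-10)

    def test_type_one_error_rate_near_nominal(self):
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            x = r.standard_normal(200)
            y = r.standard_normal(200)
            res = fit_linear_model(df_from(y=y, x=x), RegressionSpec("y", "x"))
            hits += res.p < 0.05
        assert hits / n_seeds < 0.08  # ~5% expected; allow MC slack


class TestDiagnostics:
    def fit(self, y, X):
        return sm.OLS(y, sm.add_constant(X)).fit()

    def test_model_true_data_passes(self):
        """Each diagnostic warns at its nominal ~5% rate on model-true data,
        so across seeds the pass rate must be high (single draws can warn)."""
        passes = {"normality": 0, "heteroscedasticity": 0, "linearity": 0}
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            x = r.normal(size=300)
            y = 1.0 + 0.5 * x + r.normal(size=300)
            d = model_diagnostics(self.fit(y, x))
            for key in passes:
                passes[key] += d[key]["status"] == "pass"
        for key, count in passes.items():
            assert count / n_seeds >= 0.85, key

    def test_quadratic_relation_flags_linearity(self, rng):
        x = np.linspace(-3, 3, 200)
        y = x**2 + 0.1 * rng.normal(size=200)
        d = model_diagnostics(self.fit(y, x))
        assert d["linearity"]["status"] == "warn"
        assert d["heteroscedasticity"]["status"] == "warn"  # White includes x^2

    def test_duplicated_predictor_blows_up_vif(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x + 1e-9 * rng.normal(size=100)])
        d = model_diagnostics(self.fit(rng.normal(size=100), X))
        assert d["vif"]["status"] == "warn"
        assert max(d["vif"]["values"].values()) > 1e3


class TestSuite:
    def test_suite_covers_all_predictor_outcome_pairs(self, scored_cohort):
        suite = run_association_suite(scored_cohort, subgroups=False)
        assert set(suite["predictor"]) >= {"age", "pta", "wave_v_latency", "wave_v_amplitude"}
        assert (suite["outcome"] == "composite_z").sum() >= 15
        full = suite[(suite.outcome == "composite_z") & (suite.subgroup == "full")]
        age_row = full[(full.predictor == "age") & (full.covariates == "")]
        assert age_row["B"].iloc[0] < 0  # older -> worse cognition

    def test_age_adjusted_wave_v_slopes_recover_generating_values(self):
        from abrcog.scoring import build_cognitive_scores
        from abrcog.synthetic import default_params, generate_cohort

        table, _ = generate_cohort(default_params(n_total=4000, seed=31))
        scored = build_cognitive_scores(table)
        lat = fit_linear_model(
            scored,
            RegressionSpec("composite_z", "wave_v_latency", covariates=("age",),
                           standardize=("wave_v_latency",)),
        )
        amp = fit_linear_model(
            scored,
            RegressionSpec("composite_z", "wave_v_amplitude", covariates=("age",),
                           standardize=("wave_v_amplitude",)),
        )
        assert lat.B == pytest.approx(-0.101, abs=0.025)
        assert amp.B == pytest.approx(0.110, abs=0.025)

    def test_permuted_outcome_gives_nominal_false_positive_rate(self, scored_cohort, rng):
        shuffled = scored_cohort.copy()
        shuffled["composite_z"] = rng.permutation(shuffled["composite_z"].to_numpy())
        suite = run_association_suite(
            shuffled, outcomes=["composite_z"], subgroups=False
        )
        ok = suite.dropna(subset=["p"])
        assert (ok["p"] < 0.05).mean() < 0.3  # no systematic signal survives permutation


class TestGroupComparison:
    def test_identical_groups_give_zero_difference_and_p_one(self, rng):
        vals = rng.normal(size=30)
        df = pd.DataFrame(
            {"y": np.concatenate([vals, vals]), "g": ["a"] * 30 + ["b"] * 30}
        )
        out = compare_age_groups(df, "y", group_col="g")
        pair = out["pairwise"][0]
        assert pair["mean_difference"] == pytest.approx(0.0, abs=1e-12)
        assert pair["p_bonferroni"] == pytest.approx(1.0)

    def test_null_f_p_roughly_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"y": r.standard_normal(90), "g": np.repeat(["a", "b", "c"], 30)}
            )
            ps.append(compare_age_groups(df, "y", group_col="g")["p"])
        ps = np.asarray(ps)
        # uniform p: roughly 5% below 0.05 and mean near 0.5
        assert 0.0 <= (ps < 0.05).mean() < 0.12
        assert abs(ps.mean() - 0.5) < 0.1

    def test_shifted_groups_all_pairwise_significant(self):
        sig = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "y": np.concatenate(
                        [r.standard_normal(50), r.standard_normal(50) + 1.0,
                         r.standard_normal(50) + 2.0]
                    ),
                    "g": np.repeat(["a", "b", "c"], 50),
                }
            )
            out = compare_age_groups(df, "y", group_col="g")
            sig += all(p["p_bonferroni"] < 0.01 for p in out["pairwise"])
        assert sig / n_seeds >= 0.95

    def test_single_group_rejected(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=10), "g": ["a"] * 10})
        with pytest.raises(InputError):
            compare_age_groups(df, "y", group_col="g")
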