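"""Percentile ROC sweep: labeling, AUC, Youden cutoffs, chance band."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abrcog.roc import (
    SweepConfig,
    age_adjust_cognition,
    chance_band,
    empirical_auc,
    label_by_percentile,
    run_sweep,
    youden_cutoff,
)
from abrcog.schema import DegenerateInputError, ParameterError
from conftest import brute_force_auc


class TestLabelByPercentile:
    def test_median_split_of_four_values(self):
        labels = label_by_percentile(np.array([1.0, 2.0, 3.0, 4.0]), 50)
        assert labels.tolist() == [False, False, True, True]

    def test_first_percentile_isolates_the_minimum(self):
        values = np.arange(118, dtype=float)
        labels = label_by_percentile(values, 1)
        n_poor = int((~labels).sum())
        assert 1 <= n_poor <= 2
        assert not labels[np.argmin(values)]

    def test_location_invariance(self, rng):
        values = rng.normal(size=50)
        a = label_by_percentile(values, 30)
        b = label_by_percentile(values + 10.0, 30)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_identical_values(self):
        with pytest.raises(DegenerateInputError):
            label_by_percentile(np.full(10, 3.0), 50)

    def test_percentile_bounds_enforced(self):
        with pytest.raises(ParameterError):
            label_by_percentile(np.arange(10.0), 100)


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        assert empirical_auc([1.0, 2.0, 3.0], [False, True, True]) == 1.0

    def test_tie_counted_half(self):
        # good {2,3}, poor {1,2}: pairs (2>1)+(2=2)/2+(3>1)+(3>2) = 3.5/4
        auc = empirical_auc([1.0, 2.0, 2.0, 3.0], [False, False, True, True])
        assert auc == pytest.approx(0.875)

    def test_permuted_labels_average_half(self, rng):
        scores = rng.normal(size=40)
        aucs = []
        for _ in range(500):
            labels = np.zeros(40, bool)
            labels[rng.choice(40, 15, replace=False)] = True
            aucs.append(empirical_auc(scores, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            empirical_auc([1.0, 2.0], [True, True])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_with_ties(self, data):
        n = data.draw(st.integers(3, 50))
        scores = np.array(
            data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n)), float
        )
        n_good = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, bool)
        labels[:n_good] = True
        assert empirical_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_invariance_and_label_symmetry(self, data):
        n = data.draw(st.integers(4, 40))
        scores = np.array(data.draw(st.lists(st.integers(-5, 5), min_size=n, max_size=n)), float)
        labels = np.zeros(n, bool)
        labels[: data.draw(st.integers(1, n - 1))] = True
        auc = empirical_auc(scores, labels)
        # strictly increasing transform leaves AUC unchanged
        assert empirical_auc(np.exp(scores / 3) + scores, labels) == pytest.approx(auc, abs=1e-12)
        # negating scores flips AUC around 1/2
        assert empirical_auc(-scores, labels) == pytest.approx(1.0 - auc, abs=1e-12)
        # swapping classes and negating leaves it unchanged
        assert empirical_auc(-scores, ~labels) == pytest.approx(auc, abs=1e-12)


class TestYouden:
    def test_separable_classes_midpoint(self):
        cutoff, sens, spec = youden_cutoff(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([False, False, True, True])
        )
        assert cutoff == pytest.approx(2.5)
        assert sens == 1.0 and spec == 1.0

    def test_translation_equivariance(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        c0, s0, p0 = youden_cutoff(scores, labels)
        c1, s1, p1 = youden_cutoff(scores + 7.0, labels)
        assert c1 - c0 == pytest.approx(7.0, abs=1e-9)
        assert (s1, p1) == (s0, p0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_scan_over_observed_scores(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(st.lists(st.integers(0, 9), min_size=n, max_size=n)), float)
        labels = np.zeros(n, bool)
        labels[: data.draw(st.integers(1, n - 1))] = True
        cutoff, sens, spec = youden_cutoff(scores, labels)
        j_impl = sens + spec - 1.0
        # oracle: evaluate J at every observed score used as a ">=" threshold
        good, poor = scores[labels], scores[~labels]
        j_best = max(
            (good >= thr).mean() + (poor < thr).mean() - 1.0
            for thr in np.unique(scores)
        )
        j_best = max(j_best, 0.0)  # the +/-inf cutoffs give J = 0
        assert j_impl == pytest.approx(j_best, abs=1e-12)


class TestAgeAdjust:
    def test_independent_composite_is_merely_centered(self, rng):
        comp = rng.normal(size=500)
        age = rng.uniform(18, 92, 500)
        adj = age_adjust_cognition(comp, age)
        assert np.corrcoef(adj, age)[0, 1] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(adj.mean(), 0.0, atol=1e-10)

    def test_perfectly_explained_composite_residuals_zero(self, rng):
        age = rng.uniform(18, 92, 100)
        adj = age_adjust_cognition(-0.021 * age, age)
        np.testing.assert_allclose(adj, 0.0, atol=1e-10)

    def test_constant_age_rejected(self):
        with pytest.raises(DegenerateInputError):
            age_adjust_cognition(np.arange(10.0), np.full(10, 50.0))


class TestRunSweep:
    def test_composite_as_its_own_predictor_is_perfect(self, scored_cohort):
        df = scored_cohort.copy()
        df["self"] = df["composite_z"]
        curve = run_sweep(df, SweepConfig(predictor="self"))
        assert (curve.table["auc"].dropna() == 1.0).all()

    def test_independent_predictor_hovers_at_chance(self, scored_cohort, rng):
        """Grid points share one predictor draw, so a single replicate's
        grid-mean AUC wobbles ~0.05; average replicates before asserting."""
        means = []
        for _ in range(20):
            df = scored_cohort.copy()
            df["noise"] = rng.standard_normal(len(df))
            means.append(run_sweep(df, SweepConfig(predictor="noise")).summary["mean_auc"])
        assert np.mean(means) == pytest.approx(0.5, abs=0.04)

    def test_latency_cutoff_reported_in_original_units(self, scored_cohort):
        curve = run_sweep(scored_cohort, SweepConfig.for_predictor("wave_v_latency"))
        row = curve.table[curve.table["percentile"] == 50].iloc[0]
        assert row["cutoff_direction"] == "above_cutoff_poor"
        assert 5.0 < row["cutoff"] < 7.0  # ms, inside the physiological range

    def test_age_adjustment_attenuates_auc_for_age_driven_biomarker(self, scored_cohort):
        raw = run_sweep(scored_cohort, SweepConfig.for_predictor("wave_v_latency"))
        adj = run_sweep(
            scored_cohort, SweepConfig.for_predictor("wave_v_latency", adjust_age=True)
        )
        assert adj.summary["mean_auc"] < raw.summary["mean_auc"]

    def test_sweep_determinism(self, scored_cohort):
        cfg = SweepConfig.for_predictor("wave_v_amplitude", seed=3)
        a = run_sweep(scored_cohort, cfg).table
        b = run_sweep(scored_cohort, cfg).table
        assert a.equals(b)


class TestChanceBand:
    def test_single_replicate_reproducible(self, scored_cohort):
        cfg = SweepConfig.for_predictor("wave_v_amplitude", chance_replicates=1, seed=17)
        a = chance_band(scored_cohort, cfg)
        b = chance_band(scored_cohort, cfg)
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    def test_permutation_null_agrees_with_gaussian_null(self, scored_cohort, rng):
        cfg = SweepConfig.for_predictor("wave_v_amplitude", chance_replicates=200, seed=5)
        gauss = chance_band(scored_cohort, cfg)
        # alternative null: permutations of the real predictor
        from abrcog.roc import _auc_grid, _label_grid

        comp = scored_cohort["composite_z"].to_numpy()
        masks, counts = _label_grid(comp, cfg.percentiles)
        pred = scored_cohort["wave_v_amplitude"].to_numpy()
        perm_means = [
            np.nanmean(_auc_grid(rng.permutation(pred), masks, counts)) for _ in range(200)
        ]
        assert np.mean(perm_means) == pytest.approx(gauss.mean, abs=0.01)
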