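"""Response statistics: filtering, aggregation, ranking, and the classical
tests against closed-form worked examples."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xshuffle import (
    SimulatedObserverSpec,
    condition_accuracy,
    confidence_accuracy_correlation,
    enumerate_all_conditions,
    filter_participants,
    ols_fit,
    paired_comparison,
    pearson_r,
    planted_condition_accuracies,
    simulate_trials,
    transform_ranking,
)
from xshuffle.errors import (
    DegenerateVarianceError,
    FilteringError,
    PairingError,
)


def make_trials(observer_rows):
    """Build a trial table from (observer_id, condition_id, n_correct,
    n_wrong, confidence) tuples; plus optional catch rows."""
    rows = []
    for obs, cond, n_correct, n_wrong, conf, *rest in observer_rows:
        is_catch = rest[0] if rest else False
        for i in range(n_correct):
            rows.append((obs, "human", cond, "disk", "disk", conf, 1.0, is_catch))
        for i in range(n_wrong):
            rows.append((obs, "human", cond, "disk", "square", conf, 1.0, is_catch))
    return pd.DataFrame(rows, columns=[
        "observer_id", "observer_type", "condition_id", "true_class",
        "predicted_class", "confidence", "response_time", "is_catch"])


class TestFilterParticipants:
    def test_homogeneous_cohort_keeps_everyone(self):
        trials = make_trials([(f"o{i}", "baseline", 9, 1, 3) for i in range(8)])
        kept, report = filter_participants(trials)
        assert len(report) == 0
        assert kept["observer_id"].nunique() == 8

    def test_mad_excludes_exactly_the_outlier(self):
        # 9 observers at 0.9, one at 0.1; median 0.9, MAD 0 -> any deviation
        # beyond 0 excludes only the outlier at mad_c = 3
        rows = [(f"o{i}", "grid_b20", 9, 1, 3) for i in range(9)]
        rows.append(("bad", "grid_b20", 1, 9, 3))
        kept, report = filter_participants(make_trials(rows), mad_c=3.0)
        assert report["observer_id"].tolist() == ["bad"]
        assert report["reason"].tolist() == ["mad"]
        assert kept["observer_id"].nunique() == 9

    def test_catch_failure_excluded_with_reason(self):
        rows = [(f"o{i}", "baseline", 9, 1, 3) for i in range(3)]
        rows += [(f"o{i}", "baseline", 3, 0, 3, True) for i in range(3)]
        rows.append(("sleepy", "baseline", 9, 1, 3))
        rows.append(("sleepy", "baseline", 0, 3, 3, True))
        kept, report = filter_participants(make_trials(rows), catch_min=2 / 3)
        assert ("sleepy", "catch") in set(zip(report["observer_id"],
                                              report["reason"]))
        assert "sleepy" not in set(kept["observer_id"])

    def test_all_excluded_raises(self):
        rows = [("only", "baseline", 0, 3, 3, True),
                ("only", "baseline", 5, 5, 3)]
        with pytest.raises(FilteringError):
            filter_participants(make_trials(rows))


class TestConditionAccuracy:
    def test_two_of_three_correct(self):
        trials = make_trials([("o1", "grid_b20", 2, 1, 4)])
        summary = condition_accuracy(trials)
        assert summary.loc[0, "accuracy"] == pytest.approx(2 / 3)
        assert summary.loc[0, "n_trials"] == 3
        assert summary.loc[0, "family"] == "grid"

    def test_perfect_baseline(self):
        trials = make_trials([("o1", "baseline", 5, 0, 5)])
        summary = condition_accuracy(trials)
        assert summary.loc[0, "accuracy"] == 1.0

    def test_weighted_mean_identity(self):
        trials = make_trials([("o1", "grid_b20", 2, 1, 4),
                              ("o1", "grid_b40", 5, 5, 2)])
        summary = condition_accuracy(trials)
        overall = (summary["accuracy"] * summary["n_trials"]).sum() / \
            summary["n_trials"].sum()
        raw = (trials["true_class"] == trials["predicted_class"]).mean()
        assert overall == pytest.approx(raw)

    def test_aggregation_commutes_with_partitioning(self):
        rng = np.random.default_rng(0)
        conditions = enumerate_all_conditions()[:6]
        planted = planted_condition_accuracies(conditions, rng)
        obs = [SimulatedObserverSpec(f"h{i}", "human", planted) for i in range(4)]
        trials = simulate_trials(obs, conditions, 5, rng)
        whole = condition_accuracy(trials)
        half1 = trials[trials["observer_id"].isin({"h0", "h1"})]
        half2 = trials[~trials["observer_id"].isin({"h0", "h1"})]
        merged = condition_accuracy(pd.concat([half1, half2]))
        pd.testing.assert_frame_equal(whole, merged)


class TestTransformRanking:
    def test_singleton(self):
        trials = make_trials([("o1", "grid_b20", 2, 1, 4)])
        ranking = transform_ranking(condition_accuracy(trials))
        assert len(ranking) == 1
        assert ranking.loc[0, "family"] == "grid"

    def test_known_means_give_exact_order(self):
        summaries = pd.DataFrame({
            "observer_type": "human",
            "condition_id": ["grid_b20", "full_random_p1", "baseline"],
            "family": ["grid", "full_random", "baseline"],
            "n_trials": 10,
            "accuracy": [0.5, 0.2, 0.9],
            "mean_confidence": 3.0,
        })
        ranking = transform_ranking(summaries)
        assert ranking["family"].tolist() == ["baseline", "grid", "full_random"]
        assert not ranking["tied"].any()

    def test_ties_flagged_and_alphabetical(self):
        summaries = pd.DataFrame({
            "observer_type": "human",
            "condition_id": ["grid_b20", "within_grid_b20_p0.5"],
            "family": ["grid", "within_grid"],
            "n_trials": 10,
            "accuracy": [0.5, 0.5],
            "mean_confidence": 3.0,
        })
        ranking = transform_ranking(summaries)
        assert ranking["family"].tolist() == ["grid", "within_grid"]
        assert ranking["tied"].all()

    def test_planted_difficulty_recovered(self):
        # 8 families with well-separated planted accuracies; per-condition
        # n = 150 trials gives exact rank recovery
        rng = np.random.default_rng(42)
        conditions = enumerate_all_conditions()
        family_acc = {"baseline": 0.98, "full_random": 0.9, "grid": 0.8,
                      "within_grid": 0.68, "local_structure": 0.56,
                      "seg_within": 0.44, "seg_displacement": 0.32,
                      "color_flatten": 0.2}
        planted = {s.condition_id: family_acc[s.family] for s in conditions}
        obs = [SimulatedObserverSpec(f"h{i}", "human", planted)
               for i in range(10)]
        trials = simulate_trials(obs, conditions, 15, rng)
        ranking = transform_ranking(condition_accuracy(trials))
        expected = sorted(family_acc, key=family_acc.get, reverse=True)
        assert ranking["family"].tolist() == expected


class TestPairedComparison:
    def test_identical_inputs_give_zero_t(self):
        res = paired_comparison([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_on_differences_1_2_3(self):
        res = paired_comparison([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.df == 2

    def test_df_override_changes_p_not_statistic(self):
        a, b = [1.0, 2.0, 3.0, 5.0], [0.0, 1.0, 1.0, 2.0]
        default = paired_comparison(a, b)
        override = paired_comparison(a, b, df=3)
        assert override.statistic == default.statistic
        assert default.df == 3  # n-1 happens to be 3 here
        custom = paired_comparison(a, b, df=10)
        assert custom.p_value != default.p_value or default.df == 10

    def test_antisymmetric_under_swap(self):
        a, b = [0.9, 0.8, 0.4], [0.5, 0.6, 0.3]
        assert paired_comparison(a, b).statistic == \
            pytest.approx(-paired_comparison(b, a).statistic)

    def test_degenerate_variance_flagged(self):
        with pytest.raises(DegenerateVarianceError):
            paired_comparison([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            paired_comparison([1.0, 2.0], [1.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x).estimate == pytest.approx(1.0, abs=1e-10)
        assert pearson_r(x, -x).estimate == pytest.approx(-1.0, abs=1e-10)

    def test_worked_example_r_08(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.estimate == pytest.approx(0.8, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = ols_fit(2 * x + 1, x)
        assert res.estimate == pytest.approx(2.0, abs=1e-10)
        assert res.details["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.details["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        assert ols_fit(y, x).details["r_squared"] == \
            pytest.approx(pearson_r(x, y).estimate ** 2, abs=1e-10)

    def test_permutation_null_p_values_uniform(self):
        # slope p-values under shuffled responses should be U(0,1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        pvals = [ols_fit(rng.permutation(y), x).p_value for _ in range(300)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_predictor_raises(self):
        with pytest.raises(DegenerateVarianceError):
            ols_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestConfidenceAccuracyCorrelation:
    def test_noiseless_affine_gives_r_1(self):
        # realized accuracies are exact multiples of 1/10; confidence is an
        # exact affine map of the same per-condition accuracy
        rows = []
        for i, cond in enumerate(["grid_b20", "grid_b40", "grid_b80",
                                  "full_random_p0.5", "baseline"]):
            n_correct = 2 * i + 1
            acc = n_correct / 10
            rows.append(("o1", cond, n_correct, 10 - n_correct, 1 + 4 * acc))
        trials = make_trials(rows)
        res = confidence_accuracy_correlation(trials, "human")
        assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_human_like_vs_network_like_contrast(self):
        # the behavioral signature: human confidence tracks per-condition
        # accuracy (strong positive r), network confidence does not
        rng = np.random.default_rng(3)
        conditions = enumerate_all_conditions()
        planted = planted_condition_accuracies(conditions, rng)
        humans = [SimulatedObserverSpec(f"h{i}", "human", planted)
                  for i in range(8)]
        networks = [SimulatedObserverSpec(f"n{i}", "network", planted)
                    for i in range(3)]
        trials = simulate_trials(humans + networks, conditions, 12, rng)
        human_r = confidence_accuracy_correlation(trials, "human")
        network_r = confidence_accuracy_correlation(trials, "network")
        assert human_r.estimate > 0.9
        assert abs(network_r.estimate) < 0.3

    def test_too_few_conditions_raises(self):
        trials = make_trials([("o1", "baseline", 3, 0, 5)])
        with pytest.raises(PairingError):
            confidence_accuracy_correlation(trials, "human")
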