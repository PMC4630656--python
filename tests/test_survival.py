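"""Cox fits, risk scores, log-rank, Fisher and k-means validation.

The univariate Cox fit is validated against a brute-force maximization of an
independently coded Breslow partial likelihood on small instances, and
against lifelines on tie-free data (where Breslow and Efron coincide).
"""
import numpy as np
import pandas as pd
import pytest

from gradenet.errors import (ConfigurationError, UndefinedCorrelationError)
from gradenet.survival import (RiskModel, cox_univariate, dichotomize,
                               fisher_idh, logrank, risk_scores,
                               split_train_test, validate_kmeans)
from gradenet.synth import FFLInstance


def naive_breslow_loglik(beta, x, time, event):
    """Direct double-loop Breslow partial likelihood (independent oracle)."""
    ll = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        risk = sum(np.exp(beta * x[j]) for j in range(len(x))
                   if time[j] >= time[i])
        ll += beta * x[i] - np.log(risk)
    return ll


def grid_cox(x, time, event, lo=-6, hi=6, n=24001):
    grid = np.linspace(lo, hi, n)
    ll = [naive_breslow_loglik(b, x, time, event) for b in grid]
    return grid[int(np.argmax(ll))]


def _surv(time, event):
    return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(time))],
                         "time": time, "event": event})


class TestSplit:
    def test_half_split_disjoint_exhaustive(self):
        samples = [f"s{i}" for i in range(100)]
        train, test = split_train_test(samples, seed=4)
        assert len(train) == 50 and len(test) == 50
        assert set(train) | set(test) == set(samples)
        assert set(train) & set(test) == set()

    def test_same_seed_same_split(self):
        samples = [f"s{i}" for i in range(31)]
        assert split_train_test(samples, seed=9) == split_train_test(samples, seed=9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            split_train_test(["a"] * 5, seed=0)


class TestCoxUnivariate:
    def test_matches_grid_maximization_small_instances(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 9))
            x = rng.normal(size=n)
            time = np.maximum(np.round(rng.exponential(10, size=n), 1),
                              0.1)  # rounding induces ties
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[0] = 1
            beta, _ = cox_univariate(x, _surv(time, event))
            ref = grid_cox(x, time, event)
            if abs(ref) > 5.5:  # separation: the grid hits its boundary
                continue
            assert beta == pytest.approx(ref, abs=1e-3)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.5 * x))
        event = (rng.random(n) < 0.8).astype(int)
        beta, p = cox_univariate(x, _surv(time, event))
        df = pd.DataFrame({"x": x, "time": time, "event": event})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert p == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)

    def test_null_covariate_estimates_near_zero(self, rng):
        n = 500
        x = rng.normal(size=n)
        time = rng.exponential(10, size=n)
        beta, _ = cox_univariate(x, _surv(time, np.ones(n, dtype=int)))
        assert abs(beta) < 0.1

    def test_constant_covariate_flagged(self):
        with pytest.raises(UndefinedCorrelationError):
            cox_univariate(np.ones(10), _surv(np.arange(1, 11.0),
                                              np.ones(10, dtype=int)))

    def test_no_events_rejected(self):
        with pytest.raises(ConfigurationError):
            cox_univariate(np.arange(10.0), _surv(np.arange(1, 11.0),
                                                  np.zeros(10, dtype=int)))


class TestRiskScores:
    def test_cancellation(self):
        model = RiskModel(("a", "b", "c"), (1.0, -1.0, 0.0), 0.0)
        expr = pd.DataFrame([[2.0], [2.0], [9.0]], index=["a", "b", "c"],
                            columns=["s1"])
        assert risk_scores(model, expr)["s1"] == 0.0

    def test_zero_betas_zero_scores(self, rng):
        model = RiskModel(("a", "b", "c"), (0.0, 0.0, 0.0), 0.0)
        expr = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "c"])
        assert (risk_scores(model, expr) == 0).all()

    def test_hand_arithmetic(self):
        model = RiskModel(("a", "b", "c"), (0.5, 1.0, -2.0), 0.0)
        expr = pd.DataFrame([[2.0], [3.0], [1.0]], index=["a", "b", "c"],
                            columns=["s1"])
        assert risk_scores(model, expr)["s1"] == pytest.approx(2.0)

    def test_missing_tf_rejected(self):
        model = RiskModel(("a", "b", "zz"), (1, 1, 1), 0.0)
        expr = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(ConfigurationError):
            risk_scores(model, expr)


class TestDichotomize:
    def test_median_split(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = dichotomize(scores, 2.5)
        assert (groups == ["low", "low", "high", "high"]).all()

    def test_all_equal_scores_all_low(self):
        scores = pd.Series([1.0, 1.0, 1.0])
        assert (dichotomize(scores, 1.0) == "low").all()

    def test_training_threshold_reused_on_test(self):
        test_scores = pd.Series([10.0, 20.0, 30.0])
        # training threshold 25 ignores the test median (20)
        assert dichotomize(test_scores, 25.0).tolist() == ["low", "low", "high"]


class TestLogrank:
    def test_hand_tabulated_four_sample_example(self):
        # times 1,2,3,4 all events, groups A,A,B,B:
        # O-E = 7/6, V = 17/36, chi2 = (7/6)^2 / (17/36) = 49/17
        surv = _surv(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, dtype=int))
        groups = pd.Series(["A", "A", "B", "B"],
                           index=["s0", "s1", "s2", "s3"])
        chi2, p = logrank(groups, surv)
        assert chi2 == pytest.approx(49 / 17, rel=1e-10)
        from scipy.stats import chi2 as chi2_dist
        assert p == pytest.approx(chi2_dist.sf(49 / 17, df=1), rel=1e-10)

    def test_identical_groups_give_null_statistic(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        surv = _surv(time, np.ones(6, dtype=int))
        groups = pd.Series(["A"] * 3 + ["B"] * 3,
                           index=[f"s{i}" for i in range(6)])
        chi2, p = logrank(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        n = 30
        surv = _surv(rng.exponential(5, size=n), rng.integers(0, 2, n))
        surv.loc[0, "event"] = 1
        labels = rng.choice(["A", "B"], size=n)
        labels[:2] = ["A", "B"]
        groups = pd.Series(labels, index=surv["sample_id"].tolist())
        swapped = groups.map({"A": "B", "B": "A"})
        assert logrank(groups, surv) == pytest.approx(logrank(swapped, surv))


class TestFisher:
    def test_independent_table(self):
        groups = pd.Series(["high"] * 10 + ["low"] * 10)
        idh = pd.Series((["mutant"] * 5 + ["wildtype"] * 5) * 2)
        assert fisher_idh(groups, idh) == pytest.approx(1.0)

    def test_perfect_association_hypergeometric_tail(self):
        from math import comb

        groups = pd.Series(["high"] * 10 + ["low"] * 10)
        idh = pd.Series(["mutant"] * 10 + ["wildtype"] * 10)
        assert fisher_idh(groups, idh) == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_transpose_invariance(self, rng):
        groups = pd.Series(rng.choice(["high", "low"], size=40))
        idh = pd.Series(rng.choice(["mutant", "wildtype"], size=40))
        assert fisher_idh(groups, idh) == pytest.approx(fisher_idh(idh, groups))

    def test_empty_margin_rejected(self):
        groups = pd.Series(["high"] * 4)
        idh = pd.Series(["mutant", "mutant", "wildtype", "wildtype"])
        with pytest.raises(ConfigurationError):
            fisher_idh(groups, idh)


class TestValidateKmeans:
    def _clustered_cohort(self, rng, separation=6.0, n=60):
        half = n // 2
        x = np.concatenate([rng.normal(0, 1, size=(3, half)),
                            rng.normal(separation, 1, size=(3, half))], axis=1)
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(x, index=["a", "b", "c"], columns=cols)
        time = np.concatenate([rng.exponential(20, half),
                               rng.exponential(2, half)])
        surv = pd.DataFrame({"sample_id": cols, "time": time,
                             "event": np.ones(n, dtype=int)})
        return expr, surv

    def test_separated_clusters_with_distinct_hazards_detected(self, rng):
        expr, surv = self._clustered_cohort(rng)
        p, labels = validate_kmeans(FFLInstance("a", "b", "c"), expr, surv, seed=1)
        assert p < 0.05
        assert labels.nunique() == 2

    def test_same_seed_identical_labels(self, rng):
        expr, surv = self._clustered_cohort(rng)
        _, l1 = validate_kmeans(FFLInstance("a", "b", "c"), expr, surv, seed=3)
        _, l2 = validate_kmeans(FFLInstance("a", "b", "c"), expr, surv, seed=3)
        assert l1.equals(l2)

    def test_too_few_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 4)), index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(4)])
        surv = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)],
                             "time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1]})
        with pytest.raises(ConfigurationError):
            validate_kmeans(FFLInstance("a", "b", "c"), expr, surv, seed=0)
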