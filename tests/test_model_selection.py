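"""Logistic IRLS, AUC, seeded-pair search, AIC stopping and repeated CV."""

import numpy as np
import pandas as pd
import pytest

from ibrad.cohort_stats import FeatureTable, UnivariateResult
from ibrad.model_selection import (
    ModelSpec,
    aic_forward_stop,
    auc,
    fit_logistic,
    predict_prob,
    repeated_cv,
    seeded_pair,
    third_feature_search,
)


def res(feature, cohort="A", p_adj=0.01, p_raw=None, significant=True):
    return UnivariateResult(feature, cohort, "wmw", p_raw if p_raw is not None else p_adj / 2,
                            p_adj, significant)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        m = fit_logistic(np.empty((20, 0)), np.array([0, 1] * 10))
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_closed_form(self):
        y = np.array([1] * 45 + [0] * 150)
        m = fit_logistic(np.empty((195, 0)), y)
        assert m.intercept == pytest.approx(np.log(45 / 150), abs=1e-6)
        logl = 45 * np.log(45 / 195) + 150 * np.log(150 / 195)
        assert m.aic == pytest.approx(-2 * logl + 2, abs=1e-6)

    def test_matches_reference_glm(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + rng.normal(size=40) > 0).astype(float)
        m = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [m.intercept, *m.coefficients], ref.params, atol=1e-6
        )
        assert m.aic == pytest.approx(ref.aic, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_deviance_decreases_monotonically(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 3))
        y = (X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=60) > 0).astype(float)
        m = fit_logistic(X, y)
        diffs = np.diff(m.deviance_path)
        assert np.all(diffs <= 1e-9)

    def test_perfect_separation_flagged_not_raised(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(X, y)
        assert m.separation_flag


class TestPredictProb:
    # a reference three-feature pCR model: intercept -1.590,
    # coefficients (maxFD, GLNU, energy) = (-0.507, -0.621, -1.393)
    MODEL = ModelSpec(
        features=["fd", "glnu", "energy"],
        intercept=-1.590,
        coefficients=[-0.507, -0.621, -1.393],
        aic=192.23,
    )

    def test_at_standardised_origin(self):
        assert predict_prob(self.MODEL, np.zeros(3)) == pytest.approx(
            1 / (1 + np.exp(1.590)), abs=1e-6
        )

    def test_at_unit_feature_values(self):
        z = -1.590 - 0.507 - 0.621 - 1.393
        assert predict_prob(self.MODEL, np.ones(3)) == pytest.approx(
            1 / (1 + np.exp(-z)), abs=1e-6
        )
        assert predict_prob(self.MODEL, np.ones(3)) == pytest.approx(0.0161, abs=2e-4)

    def test_extreme_margin_clipped_below_one(self):
        m = ModelSpec(features=["x"], intercept=0.0, coefficients=[1000.0], aic=0.0)
        p = predict_prob(m, np.array([100.0]))
        assert 0.999 < p < 1.0


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_half_concordant(self):
        assert auc([0.9, 0.2, 0.8, 0.1], [1, 0, 0, 1]) == 0.5

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestSeededPair:
    def test_lowest_adjusted_p_per_cohort(self):
        a = [res("f1", p_adj=0.001), res("f2", p_adj=0.02)]
        b = [res("g1", "B", p_adj=0.04), res("g2", "B", p_adj=0.003)]
        assert seeded_pair(a, b) == ("f1", "g2")

    def test_tie_breaks_lexicographically(self):
        a = [res("zeta", p_adj=0.01, p_raw=0.001), res("alpha", p_adj=0.01, p_raw=0.001)]
        b = [res("g", "B", p_adj=0.01)]
        assert seeded_pair(a, b)[0] == "alpha"

    def test_shared_top_feature_takes_runner_up(self):
        a = [res("same", p_adj=0.001)]
        b = [res("same", "B", p_adj=0.002), res("next", "B", p_adj=0.01)]
        assert seeded_pair(a, b) == ("same", "next")

    def test_no_significant_feature_is_error(self):
        a = [res("f1", significant=False, p_adj=0.5)]
        b = [res("g1", "B", p_adj=0.01)]
        with pytest.raises(ValueError, match="no seed"):
            seeded_pair(a, b)


def table_from(X, y, cohorts=None):
    idx = pd.Index([f"P{i}" for i in range(len(y))])
    cohorts = cohorts if cohorts is not None else ["A"] * len(y)
    df = pd.DataFrame(np.asarray(pd.DataFrame(X)), index=idx, columns=list(pd.DataFrame(X).columns))
    return FeatureTable(
        df, pd.Series(y, index=idx), pd.Series(cohorts, index=idx),
        require_both_classes=False,
    )


class TestThirdFeatureSearch:
    def _data(self, seed, n=120):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 4) + [0] * (n - n // 4))
        df = pd.DataFrame(
            {
                "a": y + rng.normal(0, 1.2, n),
                "b": y + rng.normal(0, 1.2, n),
                "signal": y + rng.normal(0, 0.8, n),
                **{f"noise{i}": rng.normal(size=n) for i in range(5)},
            },
            index=[f"P{i}" for i in range(n)],
        )
        return df, y.astype(float)

    def test_informative_candidate_wins_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            df, y = self._data(seed)
            m = third_feature_search(df, y, ("a", "b"), ["signal"] + [f"noise{i}" for i in range(5)])
            hits += m.features[-1] == "signal"
        assert hits >= 95

    def test_single_candidate_selected(self):
        df, y = self._data(0)
        m = third_feature_search(df, y, ("a", "b"), ["noise0"])
        assert m.features == ["a", "b", "noise0"]

    def test_duplicate_candidates_break_ties_lexicographically(self):
        df, y = self._data(1)
        df["dup_z"] = df["signal"]
        df["dup_a"] = df["signal"]
        m = third_feature_search(df, y, ("a", "b"), ["dup_z", "dup_a"])
        assert m.features[-1] == "dup_a"

    def test_empty_candidates_returns_pair_model(self):
        df, y = self._data(2)
        m = third_feature_search(df, y, ("a", "b"), [])
        assert m.features == ["a", "b"]


class TestAicForwardStop:
    def _incumbent(self, df, y):
        from ibrad.model_selection import _fit_on

        return _fit_on(df, y, ["a", "b", "signal"])

    def test_pure_noise_candidate_stop_rate_matches_chi_square_theory(self):
        # Adding one null feature improves the deviance by ~chi2(1); AIC accepts
        # it iff the improvement exceeds 2, so with 4 candidates screened by
        # training AUC the immediate-stop probability lies between
        # P(chi2_1 < 2)^4 ~ 0.505 (all four must fail) and
        # P(chi2_1 < 2) ~ 0.843 (only the best is ever evaluated).
        stops = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            y = np.array([1] * 30 + [0] * 90).astype(float)
            df = pd.DataFrame(
                {
                    "a": y + rng.normal(0, 1.2, n),
                    "b": y + rng.normal(0, 1.2, n),
                    "signal": y + rng.normal(0, 0.8, n),
                    **{f"n{i}": rng.normal(size=n) for i in range(4)},
                },
                index=[f"P{i}" for i in range(n)],
            )
            inc = self._incumbent(df, y)
            out = aic_forward_stop(df, y, inc, [f"n{i}" for i in range(4)])
            stops += out.features == inc.features
        assert 40 <= stops <= 90

    def test_duplicated_column_rejected_by_aic(self, rng):
        n = 100
        y = np.array([1] * 30 + [0] * 70).astype(float)
        df = pd.DataFrame(
            {"a": y + rng.normal(0, 1, n), "b": y + rng.normal(0, 1, n)},
            index=[f"P{i}" for i in range(n)],
        )
        df["a_copy"] = df["a"]
        from ibrad.model_selection import _fit_on

        inc = _fit_on(df, y, ["a", "b"])
        out = aic_forward_stop(df, y, inc, ["a_copy"])
        assert out.features == ["a", "b"]  # logL unchanged, +1 parameter => AIC +2

    def test_empty_candidates_returns_incumbent(self, rng):
        y = np.array([0, 1] * 20).astype(float)
        df = pd.DataFrame({"a": rng.normal(size=40)}, index=[f"P{i}" for i in range(40)])
        from ibrad.model_selection import _fit_on

        inc = _fit_on(df, y, ["a"])
        assert aic_forward_stop(df, y, inc, []).features == ["a"]


class TestRepeatedCV:
    def test_perfect_separator_scores_high(self):
        n = 60
        y = np.array([1] * 20 + [0] * 40)
        X = {"sep": y + 0.001 * np.arange(n)}
        cv = repeated_cv(table_from(X, y), ["sep"], k=10, repetitions=10, seed=0)
        assert cv.mean_auc > 0.99

    def test_pure_noise_feature_is_null(self):
        # averaged over several independent noise datasets: a single draw's
        # chance association (|r| up to ~0.2 at n=60) would dominate otherwise
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.array([1] * 20 + [0] * 40)
            X = {"noise": rng.normal(size=n)}
            aucs.append(repeated_cv(table_from(X, y), ["noise"], k=10, repetitions=10, seed=seed).mean_auc)
        assert 0.40 <= np.mean(aucs) <= 0.60

    def test_same_seed_is_bit_identical(self, rng):
        n = 50
        y = np.array([0, 1] * 25)
        X = {"f": rng.normal(size=n), "g": rng.normal(size=n)}
        t = table_from(X, y)
        cv1 = repeated_cv(t, ["f", "g"], k=5, repetitions=8, seed=7)
        cv2 = repeated_cv(t, ["f", "g"], k=5, repetitions=8, seed=7)
        np.testing.assert_array_equal(cv1.auc_per_repetition, cv2.auc_per_repetition)

    def test_label_shuffle_detects_overfitting(self, rng):
        # strong signal, then shuffled labels: training AUC stays high while
        # cross-validated AUC collapses to the null band
        n = 80
        y = np.array([1] * 25 + [0] * 55)
        X = pd.DataFrame({f"f{i}": y + rng.normal(0, 1.0, n) for i in range(10)})
        y_shuffled = rng.permutation(y)
        t = table_from(X, y_shuffled)
        from ibrad.model_selection import _fit_on

        train = _fit_on(t.features, y_shuffled.astype(float), list(X.columns))
        cv = repeated_cv(t, list(X.columns), k=10, repetitions=20, seed=3)
        assert train.train_auc > 0.7
        assert 0.40 <= cv.mean_auc <= 0.60

    def test_every_patient_scored_once_per_repetition(self):
        # partition property is what makes pooled out-of-fold AUC well-defined
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0, 1] * 15)
        folds = list(StratifiedKFold(5, shuffle=True, random_state=0).split(np.zeros(30), y))
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(30))
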