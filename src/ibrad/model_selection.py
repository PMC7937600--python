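"""Seeded-pair logistic model search with AIC stopping, and repeated CV.

The model-building strategy mirrors a two-scanner screening design: the most
significant feature of each cohort seeds a two-feature logistic model on the
merged standardised table; candidate third features (significant in at least
one cohort) are tried one at a time and the highest-training-AUC model is
kept; further features are accepted greedily only while they lower the AIC.
Robustness is measured by stratified ten-fold cross-validation repeated many
times, with fold-wise re-standardisation so no test-fold information leaks
into the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import FeatureTable, UnivariateResult

MAX_IRLS_ITER = 100
SCORE_TOL = 1e-8


@dataclass
class ModelSpec:
    """A fitted logistic model: ordered features, coefficients, AIC, train AUC."""

    features: list[str]
    intercept: float
    coefficients: list[float]
    aic: float
    train_auc: float = float("nan")
    converged: bool = True
    separation_flag: bool = False
    deviance_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.features):
            raise ValueError("one coefficient per feature required")


@dataclass
class CVResult:
    k: int
    repetitions: int
    seed: int
    auc_per_repetition: np.ndarray
    mean_auc: float
    auc_ci: tuple[float, float]  # 2.5 / 97.5 percentiles over repetitions


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None) -> ModelSpec:
    """Maximum-likelihood logistic regression by IRLS (Newton with halving).

    Converges when the maximal score component falls below 1e-8 or after 100
    iterations; step halving enforces a monotone deviance decrease. Perfect
    separation is flagged with a warning (diverging coefficients), never an
    exception. ``aic = 2 (p + 1) - 2 logL``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.size == 0:
        X = X.reshape(len(y), 0)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y lengths differ")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing values")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    names = feature_names if feature_names is not None else [f"x{i}" for i in range(p)]

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    prob = _sigmoid(Xd @ beta)
    deviance = -2.0 * _log_likelihood(y, prob)
    path = [deviance]
    converged = False
    separated = False
    for _ in range(MAX_IRLS_ITER):
        score = Xd.T @ (y - prob)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = prob * (1.0 - prob)
        hess = Xd.T @ (Xd * np.maximum(w, 1e-10)[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        # halve until the deviance does not increase
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            cand_prob = _sigmoid(Xd @ cand)
            cand_dev = -2.0 * _log_likelihood(y, cand_prob)
            if cand_dev <= deviance + 1e-12:
                break
            scale *= 0.5
        beta, prob, deviance = cand, cand_prob, cand_dev
        path.append(deviance)
        if np.max(np.abs(beta)) > 30.0:
            separated = True
            warnings.warn("possible perfect separation: coefficients diverging", stacklevel=2)
            break
    logl = -deviance / 2.0
    aic = 2.0 * (p + 1) - 2.0 * logl
    try:
        train_auc = auc(prob, y) if np.unique(y).size == 2 else float("nan")
    except ValueError:
        train_auc = float("nan")
    return ModelSpec(
        features=list(names),
        intercept=float(beta[0]),
        coefficients=[float(b) for b in beta[1:]],
        aic=float(aic),
        train_auc=train_auc,
        converged=converged,
        separation_flag=separated,
        deviance_path=path,
    )


def predict_prob(model: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Response probability 1 / (1 + exp(-(intercept + beta . x)))."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.features):
        raise ValueError(f"expected {len(model.features)} feature values, got {X.shape[1]}")
    z = model.intercept + X @ np.asarray(model.coefficients)
    prob = np.clip(_sigmoid(z), 1e-15, 1.0 - 1e-15)
    return float(prob[0]) if single else prob


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# feature search
# ---------------------------------------------------------------------------

def _most_significant(results: list[UnivariateResult], exclude: set[str] = frozenset()) -> str | None:
    sig = [r for r in results if r.significant and r.feature not in exclude]
    if not sig:
        return None
    # lowest adjusted p, ties broken on raw p then lexicographic key
    return min(sig, key=lambda r: (r.p_adj, r.p_raw, r.feature)).feature


def seeded_pair(
    results_cohort1: list[UnivariateResult], results_cohort2: list[UnivariateResult]
) -> tuple[str, str]:
    """Most significant feature of each cohort, the starting model pair.

    If both cohorts elect the same feature, cohort 2 contributes its
    runner-up instead.
    """
    a = _most_significant(results_cohort1)
    if a is None:
        raise ValueError("screening produced no seed in cohort 1")
    b = _most_significant(results_cohort2)
    if b is None:
        raise ValueError("screening produced no seed in cohort 2")
    if a == b:
        b = _most_significant(results_cohort2, exclude={a})
        if b is None:
            raise ValueError("screening produced no distinct seed in cohort 2")
    return a, b


def _fit_on(table_df: pd.DataFrame, y: np.ndarray, features: list[str]) -> ModelSpec:
    X = table_df[features].to_numpy(dtype=np.float64)
    keep = np.all(np.isfinite(X), axis=1)
    return fit_logistic(X[keep], y[keep], feature_names=features)


def third_feature_search(
    table_df: pd.DataFrame, y: np.ndarray, pair: tuple[str, str], candidates: list[str]
) -> ModelSpec:
    """Best three-feature model: pair + the candidate with highest training AUC.

    Ties break on lower AIC then lexicographic key; an empty candidate set
    returns the two-feature model.
    """
    if not candidates:
        return _fit_on(table_df, y, list(pair))
    best: tuple[float, float, str, ModelSpec] | None = None
    for cand in sorted(set(candidates) - set(pair)):
        model = _fit_on(table_df, y, [*pair, cand])
        if model.separation_flag:  # no finite MLE: AIC/AUC not comparable
            continue
        key = (-model.train_auc, model.aic, cand)
        if best is None or key < best[:3]:
            best = (*key, model)
    if best is None:
        return _fit_on(table_df, y, list(pair))
    return best[3]


def aic_forward_stop(
    table_df: pd.DataFrame, y: np.ndarray, current_model: ModelSpec, candidates: list[str]
) -> ModelSpec:
    """Greedy forward additions accepted only while the AIC decreases.

    At each round the highest-training-AUC augmented model is evaluated; it
    replaces the incumbent only if its AIC is lower, otherwise the search
    stops.
    """
    incumbent = current_model
    remaining = sorted(set(candidates) - set(incumbent.features))
    while remaining:
        best: tuple[float, float, str, ModelSpec] | None = None
        for cand in remaining:
            model = _fit_on(table_df, y, [*incumbent.features, cand])
            if model.separation_flag:  # no finite MLE: AIC/AUC not comparable
                continue
            key = (-model.train_auc, model.aic, cand)
            if best is None or key < best[:3]:
                best = (*key, model)
        if best is None:
            break
        if best[3].aic < incumbent.aic:
            incumbent = best[3]
            remaining = [c for c in remaining if c not in incumbent.features]
        else:
            break
    return incumbent


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

def _standardise_fold(
    train: np.ndarray, test: np.ndarray, cohorts_train: np.ndarray, cohorts_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cohort Z-scoring with parameters learned on the training fold only."""
    train_out = np.empty_like(train)
    test_out = np.empty_like(test)
    pooled_mean = train.mean(axis=0)
    pooled_sd = train.std(axis=0, ddof=1)
    pooled_sd = np.where(pooled_sd > 0, pooled_sd, 1.0)
    seen = np.unique(cohorts_train)
    for cohort in seen:
        tr = cohorts_train == cohort
        block = train[tr]
        if block.shape[0] >= 2:
            mean = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, pooled_sd)
        else:  # degenerate cohort slice in this fold: fall back to pooled stats
            mean, sd = pooled_mean, pooled_sd
        train_out[tr] = (block - mean) / sd
        te = cohorts_test == cohort
        if te.any():
            test_out[te] = (test[te] - mean) / sd
    unseen = ~np.isin(cohorts_test, seen)
    if unseen.any():
        test_out[unseen] = (test[unseen] - pooled_mean) / pooled_sd
    return train_out, test_out


def repeated_cv(
    table: FeatureTable,
    features: list[str],
    k: int = 10,
    repetitions: int = 300,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a fixed feature list, repeated with reshuffles.

    Per repetition the patient set is partitioned into k outcome-stratified
    folds; per fold, standardisation parameters (per cohort) and the logistic
    fit are learned on the training folds only and probabilities are
    predicted on the held-out fold. The repetition's AUC is computed on the
    pooled out-of-fold predictions; the summary is the mean and the 2.5/97.5
    percentile interval over repetitions. All randomness flows from ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold

    X_all = table.features[features].to_numpy(dtype=np.float64)
    keep = np.all(np.isfinite(X_all), axis=1)
    X_all = X_all[keep]
    y = table.outcome.to_numpy()[keep]
    cohorts = table.cohort.to_numpy()[keep]
    n = len(X_all)
    if np.unique(y).size < 2:
        raise ValueError("CV requires both outcome classes")

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(repetitions * 4).reshape(repetitions, 4)
    aucs = np.empty(repetitions)
    for rep in range(repetitions):
        scores = np.full(n, np.nan)
        for attempt in range(10):
            fold_seed = int(rep_seeds[rep, min(attempt, 3)] % (2**31 - 1))
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
            folds = list(splitter.split(np.zeros(n), y))
            if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
                break
        for tr, te in folds:
            X_tr, X_te = _standardise_fold(X_all[tr], X_all[te], cohorts[tr], cohorts[te])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic(X_tr, y[tr], feature_names=features)
            scores[te] = predict_prob(model, X_te)
        aucs[rep] = auc(scores, y)
    return CVResult(
        k=k,
        repetitions=repetitions,
        seed=seed,
        auc_per_repetition=aucs,
        mean_auc=float(aucs.mean()),
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
    )
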