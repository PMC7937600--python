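"""Two-cohort univariate screening, standardisation and homogeneity checks.

Screening runs separately within each scanner cohort: features are
Z-score-standardised per cohort (so scanner-level location/scale shifts never
masquerade as outcome signal), each feature is compared between responders
and non-responders with a t test when both outcome groups pass a
Shapiro-Wilk normality gate and a Wilcoxon-Mann-Whitney test otherwise, and
p-values are Benjamini-Hochberg adjusted across the whole screened family
within the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05
MAX_MISSING_FRACTION = 0.10


@dataclass
class FeatureTable:
    """Patients x features matrix with outcome and cohort metadata.

    ``features`` is indexed by patient id; ``outcome`` is binary pCR (1 =
    complete response) and ``cohort`` the scanner label, both aligned to the
    same index. Screening requires both outcome classes in every cohort;
    ``require_both_classes=False`` relaxes that for partial tables (single
    cohorts, invariance experiments).
    """

    features: pd.DataFrame
    outcome: pd.Series
    cohort: pd.Series
    require_both_classes: bool = True

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.outcome.index) or not self.features.index.equals(
            self.cohort.index
        ):
            raise ValueError("features, outcome and cohort must share one patient index")
        if not set(pd.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if self.require_both_classes:
            for c, grp in self.outcome.groupby(self.cohort):
                if grp.nunique() < 2:
                    raise ValueError(f"cohort {c!r} lacks one outcome class")

    @property
    def cohorts(self) -> list[str]:
        return sorted(pd.unique(self.cohort).tolist())

    def subset(self, cohort: str) -> "FeatureTable":
        keep = self.cohort == cohort
        return FeatureTable(self.features[keep], self.outcome[keep], self.cohort[keep])


@dataclass
class UnivariateResult:
    feature: str
    cohort: str
    test_used: str  # "t" | "wmw"
    p_raw: float
    p_adj: float
    significant: bool


def zscore(table: FeatureTable, scope: str = "per_cohort") -> FeatureTable:
    """Standardise each feature to sample mean 0, SD 1 within each group.

    ``scope`` is ``per_cohort`` (default — removes scanner-level shifts) or
    ``pooled``. Zero-variance features in a group are flagged missing there.
    """
    if scope not in ("per_cohort", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    df = table.features.astype(np.float64).copy()
    groups = table.cohort if scope == "per_cohort" else pd.Series("all", index=df.index)
    for _, idx in df.groupby(groups).groups.items():
        block = df.loc[idx]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        standardized = (block - mean) / sd
        standardized.loc[:, ~(sd > 0) | (block.notna().sum(axis=0) < 2)] = np.nan
        df.loc[idx] = standardized
    return FeatureTable(df, table.outcome, table.cohort)


def normality_gate(group_a: np.ndarray, group_b: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> str:
    """Choose ``"t"`` iff Shapiro-Wilk keeps normality in BOTH groups, else ``"wmw"``."""
    for g in (group_a, group_b):
        g = np.asarray(g, dtype=np.float64)
        if g.size < 3 or np.unique(g).size < 2:
            return "wmw"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(g).pvalue <= alpha:
                return "wmw"
    return "t"


def univariate_test(values: np.ndarray, outcome: np.ndarray, test: str) -> float:
    """Two-sided two-group comparison p-value.

    WMW uses exact enumeration when both groups have <= 8 observations and
    there are no ties, otherwise the tie-corrected normal approximation with
    continuity correction. The t test is Student's (pooled variance).
    """
    values = np.asarray(values, dtype=np.float64)
    outcome = np.asarray(outcome)
    g0, g1 = values[outcome == 0], values[outcome == 1]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both outcome groups must be non-empty")
    if np.unique(values).size < 2:
        return 1.0
    if test == "t":
        p = stats.ttest_ind(g0, g1, equal_var=True).pvalue
    elif test == "wmw":
        has_ties = np.unique(values).size < values.size
        if g0.size <= 8 and g1.size <= 8 and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        p = stats.mannwhitneyu(g0, g1, alternative="two-sided", method=method, use_continuity=True).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    if not np.isfinite(p):
        return 1.0
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_cohort(
    table: FeatureTable,
    cohort: str,
    alpha: float = 0.05,
    max_missing: float = MAX_MISSING_FRACTION,
) -> list[UnivariateResult]:
    """Univariate screening of every feature within one cohort.

    Features missing in more than ``max_missing`` of the cohort's patients
    are excluded; remaining missing values drop the affected patients
    pairwise. BH adjustment runs across all tested features of the cohort,
    and significance is ``p_adj < alpha``.
    """
    sub = table.subset(cohort)
    y = sub.outcome.to_numpy()
    tested: list[tuple[str, str, float]] = []
    for name in sub.features.columns:
        col = sub.features[name].to_numpy(dtype=np.float64)
        ok = np.isfinite(col)
        if (~ok).mean() > max_missing:
            continue
        v, o = col[ok], y[ok]
        if np.unique(o).size < 2 or min((o == 0).sum(), (o == 1).sum()) < 3:
            continue
        test = normality_gate(v[o == 0], v[o == 1])
        p = univariate_test(v, o, test)
        tested.append((name, test, p))
    if not tested:
        return []
    adj = bh_adjust([t[2] for t in tested])
    return [
        UnivariateResult(name, cohort, test, p, float(pa), bool(pa < alpha))
        for (name, test, p), pa in zip(tested, adj)
    ]


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either variance is zero."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_corr needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def homogeneity_tests(
    clinical: pd.DataFrame,
    cohort_col: str = "cohort",
    variables: list[str] | None = None,
) -> dict[str, float]:
    """Between-cohort homogeneity p-values for clinical covariates.

    Categorical variables use Pearson's chi-square with Yates continuity
    correction on the contingency table (the convention that reproduces the
    printed two-cohort response comparison); continuous variables use WMW.
    """
    cohorts = pd.unique(clinical[cohort_col])
    if len(cohorts) != 2:
        raise ValueError("homogeneity_tests expects exactly 2 cohorts")
    if variables is None:
        variables = [c for c in clinical.columns if c != cohort_col]
    out: dict[str, float] = {}
    for var in variables:
        col = clinical[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 10:
            a = col[clinical[cohort_col] == cohorts[0]].dropna()
            b = col[clinical[cohort_col] == cohorts[1]].dropna()
            out[var] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            contingency = pd.crosstab(col, clinical[cohort_col]).to_numpy()
            out[var] = float(chi2_yates(contingency))
    return out


def chi2_yates(contingency: np.ndarray) -> float:
    """Continuity-corrected Pearson chi-square p-value for a contingency table."""
    contingency = np.asarray(contingency, dtype=np.float64)
    expected = stats.contingency.expected_freq(contingency)
    if expected.min() < 1:
        warnings.warn("expected cell count below 1; chi-square approximation is poor", stacklevel=2)
    if np.allclose(contingency, expected):
        return 1.0
    return float(stats.chi2_contingency(contingency, correction=True)[1])
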