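"""GLM-based group inference, FDR, and age-adjusted correlations.

The inferential workhorse is ordinary least squares on small design
matrices (intercept, group indicator, age, optionally group x age), with
t-statistics and two-sided Student-t p-values.  Group effects are
reported with the convention **TD minus ASD**: a measure that is higher
in the clinical (ASD) group yields a negative coefficient and t, the
convention used for reporting hyper-connectivity.

Multiple comparisons across regions are corrected with the
Benjamini-Hochberg false-discovery-rate procedure applied separately
within each hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "CorrelationResult",
    "InteractionResult",
    "fit_ols",
    "group_difference_test",
    "interaction_test",
    "pergroup_age_correlation",
    "fdr_within_hemisphere",
    "clinical_correlation",
    "rank_sum_test",
    "sample_with_moments",
]

#: group indicator used throughout: TD = 1, ASD = 0, so the group
#: coefficient estimates TD - ASD.
_GROUP_CODE = {"TD": 1.0, "ASD": 0.0}


@dataclass(frozen=True)
class StatResult:
    """Inference for one model term."""

    term: str
    coef: float
    se: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    """(Partial) correlation coefficient with its two-sided p-value."""

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class InteractionResult:
    """Age-by-group interaction inference plus the per-group fitted slopes."""

    interaction: StatResult
    slope_td: float
    slope_asd: float


def _group_indicator(group_labels) -> np.ndarray:
    try:
        return np.asarray([_GROUP_CODE[g] for g in group_labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown group label {exc.args[0]!r}") from None


def fit_ols(response, design_matrix, term_names: list[str]) -> list[StatResult]:
    """Ordinary least squares with per-term t and two-sided p.

    ``design_matrix`` is (n, p) including any intercept column.  The
    residual degrees of freedom are ``n - p``.  A rank-deficient design
    raises, naming the offending columns.  An exact (zero-residual) fit
    yields infinite t and p = 0 for nonzero coefficients — degenerate
    but deterministic.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    if len(term_names) != p:
        raise ValueError("term_names length must equal design width")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diagonal(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    if np.any(diag <= tol):
        bad = [term_names[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - p
    rss = float(resid @ resid)
    # numerically-exact fit: residuals at floating-point rounding level
    if rss <= n * np.finfo(float).eps * max(1.0, float(y @ y)):
        rss = 0.0
    sigma2 = rss / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diagonal(cov))
    results = []
    for i, name in enumerate(term_names):
        if se[i] == 0.0:
            t = np.inf * np.sign(coef[i]) if coef[i] != 0 else 0.0
            pval = 0.0 if coef[i] != 0 else 1.0
        else:
            t = coef[i] / se[i]
            pval = 2.0 * sps.t.sf(abs(t), df)
        results.append(StatResult(name, float(coef[i]), float(se[i]), float(t), df, float(pval)))
    return results


def group_difference_test(values, group_labels, ages) -> StatResult:
    """Group difference adjusted for age: value ~ intercept + group + age.

    Returns the group term with the TD - ASD sign convention.  When age
    is constant across subjects the age column is dropped (it would be
    collinear with the intercept) and the test reduces exactly to the
    pooled two-sample t-test.
    """
    y = np.asarray(values, dtype=float)
    g = _group_indicator(group_labels)
    age = np.asarray(ages, dtype=float)
    if np.ptp(age) == 0:
        X = np.column_stack([np.ones_like(y), g])
        names = ["intercept", "group"]
    else:
        X = np.column_stack([np.ones_like(y), g, age])
        names = ["intercept", "group", "age"]
    return fit_ols(y, X, names)[1]


def interaction_test(values, group_labels, ages) -> InteractionResult:
    """Age-by-group interaction: value ~ intercept + group + age + group x age.

    The interaction coefficient is the TD slope minus the ASD slope
    (positive when the control group matures faster).  Per-group fitted
    slopes are returned alongside the interaction inference.
    """
    y = np.asarray(values, dtype=float)
    g = _group_indicator(group_labels)
    age = np.asarray(ages, dtype=float)
    X = np.column_stack([np.ones_like(y), g, age, g * age])
    res = fit_ols(y, X, ["intercept", "group", "age", "group_x_age"])
    slope_asd = res[2].coef  # baseline (ASD = 0) age slope
    slope_td = res[2].coef + res[3].coef
    return InteractionResult(interaction=res[3], slope_td=slope_td, slope_asd=slope_asd)


def pergroup_age_correlation(values, ages, group_labels) -> dict[str, CorrelationResult]:
    """Pearson correlation of a measure with age, within each group."""
    y = np.asarray(values, dtype=float)
    age = np.asarray(ages, dtype=float)
    labels = np.asarray(group_labels)
    out: dict[str, CorrelationResult] = {}
    for grp in dict.fromkeys(labels.tolist()):  # preserve encounter order
        m = labels == grp
        r, p = sps.pearsonr(age[m], y[m])
        out[str(grp)] = CorrelationResult(r=float(r), p=float(p), n=int(m.sum()))
    return out


def fdr_within_hemisphere(p_values, hemispheres, q: float = 0.05):
    """Benjamini-Hochberg step-up applied separately per hemisphere.

    Returns ``(rejected, p_adjusted)`` aligned with the input.  NaN
    p-values (untestable regions) are passed through as NaN/not
    rejected and do not count toward either hemisphere's family.
    """
    p = np.asarray(p_values, dtype=float)
    hemi = np.asarray(hemispheres)
    rejected = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    for h in np.unique(hemi):
        m = (hemi == h) & np.isfinite(p)
        if not m.any():
            continue
        rej, adj, _, _ = multipletests(p[m], alpha=q, method="fdr_bh")
        rejected[m] = rej
        adjusted[m] = adj
    return rejected, adjusted


def clinical_correlation(metric_values, clinical_scores, ages) -> CorrelationResult:
    """Partial correlation of a network measure with a clinical score,
    controlling for age.

    Both variables are residualised on (intercept, age) and the Pearson
    correlation of the residuals is returned, with a two-sided p from
    the t-distribution on n - 3 degrees of freedom.  Equivalent to the
    score term of the GLM metric ~ score + age.
    """
    y = np.asarray(metric_values, dtype=float)
    s = np.asarray(clinical_scores, dtype=float)
    age = np.asarray(ages, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("partial correlation needs at least 4 observations")
    X = np.column_stack([np.ones(n), age])
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta_s, *_ = np.linalg.lstsq(X, s, rcond=None)
    ry, rs = y - X @ beta_y, s - X @ beta_s
    r = float(np.dot(ry, rs) / np.sqrt(np.dot(ry, ry) * np.dot(rs, rs)))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n)


def sample_with_moments(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw a normal sample rescaled to the exact mean and sample SD.

    Useful for reconstructing worked examples from published summary
    statistics: any statistic that depends on the data only through the
    first two sample moments (e.g. the pooled two-sample t) is then
    reproduced exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2 to fix a sample SD")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have at most 10 observations
    and there are no ties; normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    exact = len(a) <= 10 and len(b) <= 10 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if exact else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
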