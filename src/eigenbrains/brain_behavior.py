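"""Relating subject scores to clinical variables and comparing groups.

Regressions report standardized coefficients: both the outcome and all
predictors are z-scored on the listwise-complete analysis subsample, so
a beta equals the expected SD change in outcome per SD of predictor.
Missing data are handled by listwise deletion per outcome model, never
imputation.  Per-beta significance is a two-sided t-test without
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "composite_score",
    "fit_multivariable",
    "compare_groups_anova",
    "compare_groups_chisq",
    "spatial_decode",
]


@dataclass
class RegressionResult:
    outcome: str
    n_used: int
    betas: np.ndarray
    beta_pvalues: np.ndarray
    r2: float
    r2_adj: float
    model_pvalue: float
    predictor_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-term table."""
        names = self.predictor_names or [f"component_{k + 1}" for k in range(len(self.betas))]
        return pd.DataFrame({
            "outcome": self.outcome,
            "term": names,
            "beta": self.betas,
            "p_value": self.beta_pvalues,
            "n_used": self.n_used,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "model_pvalue": self.model_pvalue,
        })


@dataclass
class GroupComparison:
    variable: str
    group_names: list[str]
    group_n: list[int]
    group_mean: list[float]
    group_sd: list[float]
    statistic: float
    statistic_name: str  # "F" or "chi2"
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def composite_score(test_scores) -> float:
    """Average the available scaled scores in one cognitive domain.

    Missing tests are skipped; a fully missing domain yields NaN.
    Discontinued tests must already be coded as scaled score 1 upstream.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in np.atleast_1d(test_scores)], dtype=float
    )
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def fit_multivariable(scores: np.ndarray, outcome: np.ndarray, outcome_name: str = "outcome",
                      predictor_names: list[str] | None = None) -> RegressionResult:
    """OLS of a standardized outcome on standardized component scores.

    Rows with any missing value (outcome or any predictor) are dropped
    (listwise deletion); standardization uses the retained subsample.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    outcome = np.asarray(outcome, dtype=float)
    if outcome.shape[0] != scores.shape[0]:
        raise ValueError("outcome length must match number of score rows")
    k = scores.shape[1]

    keep = ~(np.isnan(outcome) | np.isnan(scores).any(axis=1))
    x = scores[keep]
    y = outcome[keep]
    n_used = int(keep.sum())
    if n_used < k + 2:
        raise ValueError(f"only {n_used} complete rows for {k} predictors (need >= {k + 2})")
    if np.std(y, ddof=1) == 0:
        raise ValueError(f"outcome {outcome_name!r} is constant on the analysis subsample")
    if np.any(np.std(x, axis=0, ddof=1) == 0):
        raise ValueError("a predictor is constant on the analysis subsample")

    zx = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(zx)).fit()
    return RegressionResult(
        outcome=outcome_name,
        n_used=n_used,
        betas=np.asarray(model.params[1:]),
        beta_pvalues=np.asarray(model.pvalues[1:]),
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        model_pvalue=float(model.f_pvalue),
        predictor_names=list(predictor_names) if predictor_names else [],
    )


def compare_groups_anova(values: np.ndarray, labels, variable: str = "") -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Unbalanced groups use the Tukey-Kramer form (studentized range on
    size-weighted standard errors).  Groups with fewer than 2 non-missing
    values are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        vals = values[labels == g]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            warnings.warn(f"group {g!r} has < 2 non-missing values; excluded", stacklevel=2)
            continue
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 non-missing values")

    names = list(groups)
    samples = [groups[g] for g in names]
    degenerate = np.ptp(np.concatenate(samples)) == 0
    if degenerate:
        f_stat, p = 0.0, 1.0  # all observations identical: no effect by definition
    else:
        f_stat, p = stats.f_oneway(*samples)
        f_stat, p = float(f_stat), float(p)

    pairwise: dict[tuple[str, str], float] = {}
    tukey = None if degenerate else stats.tukey_hsd(*samples)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pairwise[(names[a], names[b])] = (
                1.0 if tukey is None else float(tukey.pvalue[a, b]))

    return GroupComparison(
        variable=variable,
        group_names=names,
        group_n=[int(v.size) for v in samples],
        group_mean=[float(v.mean()) for v in samples],
        group_sd=[float(v.std(ddof=1)) for v in samples],
        statistic=f_stat,
        statistic_name="F",
        p_value=p,
        pairwise=pairwise,
    )


def compare_groups_chisq(table: np.ndarray, variable: str = "") -> GroupComparison:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("counts must be nonnegative numbers")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("a cell has expected count 0 (empty row or column)")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    col_n = table.sum(axis=0)
    return GroupComparison(
        variable=variable,
        group_names=[f"group_{j}" for j in range(table.shape[1])],
        group_n=[int(v) for v in col_n],
        group_mean=[float("nan")] * table.shape[1],
        group_sd=[float("nan")] * table.shape[1],
        statistic=float(chi2),
        statistic_name="chi2",
        p_value=float(p),
    )


def spatial_decode(eigenbrain: np.ndarray, reference_maps: dict[str, np.ndarray],
                   mask: np.ndarray | None = None) -> dict[str, float]:
    """Pearson correlation between a voxel-loading map and named reference maps.

    Purely descriptive; no p-values are computed.  Maps may be given as
    flat masked vectors (mask=None) or 3D volumes with a boolean mask.
    """
    def _vec(m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        return m[mask] if mask is not None else m.ravel()

    target = _vec(eigenbrain)
    if np.ptp(target) == 0:
        raise ValueError("the loading map is constant within the mask")
    out: dict[str, float] = {}
    for name, ref in reference_maps.items():
        vec = _vec(ref)
        if vec.shape != target.shape:
            raise ValueError(f"reference map {name!r} does not share the mask")
        if np.ptp(vec) == 0:
            raise ValueError(f"reference map {name!r} is constant within the mask")
        out[name] = float(np.corrcoef(target, vec)[0, 1])
    return out
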