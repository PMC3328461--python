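"""Statistical layer: rank-based partial correlation and group comparisons.

The centrepiece is the Spearman partial correlation with covariate
adjustment: x, y and every covariate column are rank-transformed
(average ranks for ties), the ranked x and y are residualised on the
ranked covariates by least squares, and the Pearson correlation of the
residuals is reported.  Significance uses

    t = rho * sqrt((n - 2 - k) / (1 - rho^2)),   df = n - 2 - k,

two-sided, where k is the number of covariates.  With k = 0 this is the
ordinary Spearman correlation.

Group comparisons follow the cohort-study conventions: ANCOVA (a linear
model with a group indicator plus covariates) for continuous outcomes,
pooled-variance two-sample t-tests for demographics, Fisher's exact
test for 2x2 proportions.  The cholesterol outlier rule flags subjects
whose total cholesterol exceeds their group mean by more than a stated
number of group SDs; flagged subjects are excluded from downstream
correlation analyses.  Results are reported without multiple-comparison
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import BASIC_COVARIATES, CLINICAL_VARS, LIPID_VARS, ROI_VARS

__all__ = [
    "PartialCorrResult",
    "GroupComparison",
    "spearman_partial",
    "ancova_compare",
    "two_sample_t",
    "two_sample_t_from_stats",
    "fisher_exact_2x2",
    "detect_cholesterol_outliers",
    "build_correlation_table",
    "build_group_table",
]

COVARIATE_SETS = {
    "basic": list(BASIC_COVARIATES),
    "extended": list(BASIC_COVARIATES) + list(CLINICAL_VARS),
}


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int
    k: int
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    adjusted_difference: float  # case minus control
    p: float
    covariates: tuple[str, ...]
    n_case: int
    n_control: int


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman_partial(
    x,
    y,
    covariates=None,
    covariate_names: tuple[str, ...] | None = None,
) -> PartialCorrResult:
    """Spearman partial correlation of x and y given covariate columns.

    ``covariates`` is an (n, k) array-like (or None / empty for the
    plain Spearman correlation).  All columns are rank-transformed
    before residualisation, so the statistic is invariant to monotone
    transforms of x, y, or any covariate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariate rows must match x/y length")
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant x or y after ranking: correlation undefined")
    if k == 0:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        RZ = np.column_stack([_rank(Z[:, j]) for j in range(k)])
        D = np.column_stack([np.ones(n), RZ])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            bad = _collinear_columns(RZ, covariate_names)
            raise ValueError(f"collinear covariates: {bad}")
        coef_x, *_ = np.linalg.lstsq(D, rx, rcond=None)
        coef_y, *_ = np.linalg.lstsq(D, ry, rcond=None)
        ex = rx - D @ coef_x
        ey = ry - D @ coef_y
        denom = np.sqrt((ex @ ex) * (ey @ ey))
        if denom == 0:
            raise ValueError("residuals are constant: correlation undefined")
        rho = float((ex @ ey) / denom)
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    names = tuple(covariate_names) if covariate_names else tuple(
        f"z{j}" for j in range(k)
    )
    return PartialCorrResult(rho=rho, p=p, n=n, k=k, covariates=names[:k])


def _collinear_columns(Z: np.ndarray, names) -> str:
    names = list(names) if names else [f"z{j}" for j in range(Z.shape[1])]
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(Z.shape[1]):
        cand = np.column_stack([np.ones(Z.shape[0])] + [Z[:, i] for i in keep]
                               + [Z[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            dropped.append(names[j])
    return ", ".join(dropped) if dropped else "unidentified"


def ancova_compare(outcome, group, covariates=None,
                   covariate_names: tuple[str, ...] = ()) -> GroupComparison:
    """Linear-model group comparison with covariate adjustment.

    ``group`` is a two-level vector; the reported difference is
    level2 - level1 with levels in sorted order, except that the pair
    (PD, control) is oriented as PD - control.  p is the two-sided
    t-test on the group coefficient (equivalent to the one-df F test).
    """
    y = np.asarray(outcome, dtype=float).ravel()
    g = np.asarray(group)
    levels = sorted(pd.unique(g).tolist())
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    if set(levels) == {"PD", "control"}:
        levels = ["control", "PD"]
    ind = (g == levels[1]).astype(float)
    cols = [np.ones_like(y), ind]
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
    X = np.column_stack(cols)
    n1, n2 = int((ind == 0).sum()), int((ind == 1).sum())
    if min(n1, n2) < X.shape[1] - 1:
        raise ValueError("each group needs n >= number of covariates + 2")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    fit = sm.OLS(y, X).fit()
    return GroupComparison(
        adjusted_difference=float(fit.params[1]),
        p=float(fit.pvalues[1]),
        covariates=tuple(covariate_names),
        n_case=n2,
        n_control=n1,
    )


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled t-test from summary statistics (mean, SD, n per group)."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=True)
    return float(t), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p sums the probabilities of all tables (with the
    observed margins) no more probable than the observed one under the
    hypergeometric null.
    """
    T = np.asarray(table)
    if T.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(T < 0) or not np.issubdtype(T.dtype, np.integer) and np.any(
        T != np.round(T)
    ):
        raise ValueError("table must hold non-negative integers")
    if np.any(T < 0):
        raise ValueError("table must hold non-negative integers")
    _, p = sps.fisher_exact(T.astype(int), alternative="two-sided")
    return float(p)


def detect_cholesterol_outliers(
    records: pd.DataFrame,
    threshold_sd: float = 2.0,
    value_col: str = "total_chol",
    group_col: str = "group",
) -> pd.Series:
    """Flag subjects whose cholesterol exceeds group mean + t * group SD.

    Mean and SD are computed per group including the candidate.  Returns
    a boolean Series aligned with ``records``.
    """
    counts = records.groupby(group_col)[value_col].count()
    if (counts < 3).any():
        raise ValueError("each group needs at least 3 records")
    g = records.groupby(group_col)[value_col]
    mean = g.transform("mean")
    sd = g.transform("std")
    flags = records[value_col] > mean + threshold_sd * sd
    flags.name = "chol_outlier"
    return flags


def _encode_covariates(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = []
    for c in names:
        if c == "gender":
            cols.append((df["gender"].astype(str) == "F").astype(float))
        elif c == "statin":
            cols.append(df["statin"].astype(float))
        else:
            cols.append(df[c].astype(float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def build_correlation_table(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = LIPID_VARS + CLINICAL_VARS,
    covariate_sets: dict[str, list[str]] | None = None,
    groups: tuple[str, ...] = ("PD", "control"),
    rois: tuple[str, ...] = ROI_VARS,
    alpha: float = 0.05,
    exclude_outliers: bool = True,
    outlier_threshold_sd: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Partial-correlation table: (ROI x variable x group x covariate set).

    Complete-case analysis per cell; cholesterol outliers (group mean +
    threshold SD rule) are excluded first when ``exclude_outliers``.
    Cells whose variable or covariates are structurally missing for a
    group (clinical scores in controls) are skipped.  Returns the tidy
    table and a log of exclusions / per-cell n.
    """
    covariate_sets = covariate_sets or COVARIATE_SETS
    log: dict = {"outliers_excluded": [], "cells": {}}
    df = cohort
    if exclude_outliers:
        flags = detect_cholesterol_outliers(df, outlier_threshold_sd)
        log["outliers_excluded"] = df.loc[flags, "subject_id"].tolist()
        df = df.loc[~flags]
    rows = []
    for group in groups:
        sub = df[df["group"] == group]
        for set_name, covs in covariate_sets.items():
            needed_any = [c for c in covs if c not in ("gender", "statin")]
            if sub[needed_any].isna().all().any():
                continue  # covariate set unavailable for this group
            for var in variables:
                if var not in sub or sub[var].isna().all():
                    continue
                if var in covs:
                    continue
                for roi in rois:
                    roi_col = f"r2star_{roi}"
                    use = sub[[roi_col, var, "gender", "statin"]
                              + needed_any].dropna()
                    if len(use) <= len(covs) + 2:
                        log["cells"][f"{group}/{set_name}/{roi}/{var}"] = {
                            "n": int(len(use)), "skipped": "n <= k + 2",
                        }
                        continue
                    Z = _encode_covariates(use, covs)
                    keep = [j for j in range(Z.shape[1])
                            if np.ptp(Z[:, j]) > 0]
                    if len(keep) < len(covs):
                        dropped = [covs[j] for j in range(Z.shape[1])
                                   if j not in keep]
                        log["cells"].setdefault(
                            f"{group}/{set_name}/{roi}/{var}", {}
                        )["constant_covariates_dropped"] = dropped
                    res = spearman_partial(
                        use[roi_col], use[var], Z[:, keep],
                        covariate_names=tuple(covs[j] for j in keep),
                    )
                    rows.append({
                        "group": group, "roi": roi, "variable": var,
                        "covariate_set": set_name, "rho": res.rho, "p": res.p,
                        "n": res.n, "significant": res.p < alpha,
                    })
                    log["cells"].setdefault(
                        f"{group}/{set_name}/{roi}/{var}", {}
                    ).update({"n": res.n, "df": res.n - 2 - res.k})
    return pd.DataFrame(rows), log


def build_group_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table: demographics, lipids, and regional R2*.

    Age uses the pooled t-test; gender and statin use Fisher's exact
    test; lipids and R2* use ANCOVA adjusted for age, gender and statin.
    """
    pd_df = cohort[cohort["group"] == "PD"]
    ct_df = cohort[cohort["group"] == "control"]
    rows = []
    t, p = two_sample_t(pd_df["age"], ct_df["age"])
    rows.append({"field": "age", "test": "t", "pd_mean": pd_df["age"].mean(),
                 "control_mean": ct_df["age"].mean(), "p": p})
    for field in ("gender", "statin"):
        if field == "gender":
            a = [(pd_df["gender"] == "F").sum(), (pd_df["gender"] == "M").sum()]
            b = [(ct_df["gender"] == "F").sum(), (ct_df["gender"] == "M").sum()]
        else:
            a = [pd_df["statin"].sum(), (~pd_df["statin"].astype(bool)).sum()]
            b = [ct_df["statin"].sum(), (~ct_df["statin"].astype(bool)).sum()]
        p = fisher_exact_2x2(np.array([a, b], dtype=int))
        rows.append({"field": field, "test": "fisher", "pd_mean": np.nan,
                     "control_mean": np.nan, "p": p})
    covs = _encode_covariates(cohort, COVARIATE_SETS["basic"])
    covs = covs[:, [j for j in range(covs.shape[1]) if np.ptp(covs[:, j]) > 0]]
    for field in list(LIPID_VARS) + [f"r2star_{r}" for r in ROI_VARS]:
        res = ancova_compare(
            cohort[field], cohort["group"], covs,
            covariate_names=tuple(COVARIATE_SETS["basic"]),
        )
        rows.append({
            "field": field, "test": "ancova",
            "pd_mean": pd_df[field].mean(),
            "control_mean": ct_df[field].mean(), "p": res.p,
        })
    return pd.DataFrame(rows)
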