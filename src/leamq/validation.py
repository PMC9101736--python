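"""Validation statistics: test-retest ICC, covariate-adjusted association
screen, ROC/Youden threshold selection with a minimum-sensitivity
retention rule, and two-sample comparisons from raw data or printed
summary statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    k: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    ms_subjects: float = math.nan
    ms_error: float = math.nan


def icc_test_retest(
    test: Sequence[float],
    retest: Sequence[float],
    absolute_agreement: bool = False,
    ci_level: float = 0.95,
) -> ICCResult:
    """Single-measure two-way mixed-model ICC for a test-retest design.

    The default is the consistency form ICC(3,1),
    ``(MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)`` with
    k = 2 occasions, which is invariant to an additive shift between
    occasions (systematic learning/drift does not count against
    reliability).  ``absolute_agreement=True`` switches to the
    absolute-agreement form, which penalises occasion mean differences.

    The confidence interval is the exact F-based interval for the
    consistency form; for absolute agreement it is omitted.
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValidationError("ICC requires at least 3 subjects with both administrations")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    occ_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_occ = n * ((occ_means - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_occ
    msb = ss_subj / (n - 1)
    msc = ss_occ / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msb <= 0 or np.isclose(msb, 0):
        warnings.warn("zero between-subject variance; ICC defined as 0")
        return ICCResult(0.0, "ICC(3,1) consistency", n, k, ms_subjects=msb, ms_error=mse)

    if absolute_agreement:
        icc = (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
        return ICCResult(icc, "ICC(A,1) absolute agreement", n, k, ms_subjects=msb, ms_error=mse)

    if mse == 0:
        icc, lo, hi = 1.0, 1.0, 1.0
    else:
        icc = (msb - mse) / (msb + (k - 1) * mse)
        # exact interval from the F ratio (two-way consistency form)
        alpha = 1 - ci_level
        f_obs = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    return ICCResult(icc, "ICC(3,1) consistency", n, k, lo, hi, msb, mse)


def icc_per_item(test_items: pd.DataFrame, retest_items: pd.DataFrame) -> pd.Series:
    """ICC(3,1) for each item column shared by the two administrations."""
    common = [c for c in test_items.columns if c in retest_items.columns]
    out = {}
    for c in common:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[c] = icc_test_retest(test_items[c], retest_items[c]).icc
    return pd.Series(out, name="icc")


def drop_unreliable_items(item_iccs: pd.Series, cutoff: float = 0.5):
    """Split items into (retained, dropped) by the ICC cutoff.

    Items whose test-retest ICC falls below ``cutoff`` are removed from
    further scoring, mirroring the instrument-revision step of the
    validation procedure.
    """
    dropped = sorted(item_iccs.index[item_iccs < cutoff])
    retained = [i for i in item_iccs.index if i not in dropped]
    return retained, dropped


# ---------------------------------------------------------------------------
# association screen
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    outcome_id: str
    predictor_id: str
    model: str  # "linear" | "logistic"
    slope: float
    se: float
    p_value: float
    n: int
    covariates: tuple = ()
    warning: str = ""


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def fit_association(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = ("age", "bmi", "elite"),
    centre_col: Optional[str] = "centre",
) -> AssociationResult:
    """Covariate-adjusted regression of one clinical outcome on one
    screening variable.

    Continuous outcomes use OLS, binary (0/1) outcomes logistic
    regression; the reported slope/SE/p are the Wald statistics for the
    screening variable.  Analysis is complete-case for the columns used;
    centre enters as a categorical covariate only when more than one
    centre is present among those rows.  Collinear covariate columns are
    dropped; separation in the logistic fit yields a flagged result
    rather than an exception.
    """
    import statsmodels.api as sm

    cols = [outcome, predictor] + [c for c in covariates if c in data.columns]
    use_centre = centre_col is not None and centre_col in data.columns
    sub = data[cols + ([centre_col] if use_centre else [])].dropna(
        subset=[c for c in cols]
    )
    n = len(sub)
    used_covs = [c for c in covariates if c in data.columns]
    if n < len(cols) + 2:
        return AssociationResult(outcome, predictor, "linear", math.nan, math.nan,
                                 math.nan, n, tuple(used_covs), "insufficient data")

    y = pd.to_numeric(sub[outcome], errors="coerce").to_numpy(float)
    X = pd.DataFrame({predictor: pd.to_numeric(sub[predictor], errors="coerce")})
    for c in used_covs:
        X[c] = pd.to_numeric(sub[c], errors="coerce")
    if use_centre and sub[centre_col].nunique() > 1:
        X = pd.concat(
            [X, pd.get_dummies(sub[centre_col], prefix="centre", drop_first=True, dtype=float)],
            axis=1,
        )
        used_covs = used_covs + ["centre"]
    X = sm.add_constant(X, has_constant="add")

    # drop exactly collinear columns (keep the predictor and intercept)
    warn = ""
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        keep = ["const", predictor]
        for c in [c for c in X.columns if c not in keep]:
            trial = X[keep + [c]].to_numpy(float)
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(c)
        dropped_cols = [c for c in X.columns if c not in keep]
        X = X[keep]
        warn = f"dropped collinear covariates {dropped_cols}"

    binary = _is_binary(y)
    try:
        if binary:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True) or np.isnan(fit.bse[predictor]) \
               or fit.bse[predictor] > 1e3:
                warn = (warn + "; " if warn else "") + "possible separation"
        else:
            fit = sm.OLS(y, X).fit()
    except Exception as exc:  # separation / singular fit
        return AssociationResult(outcome, predictor, "logistic" if binary else "linear",
                                 math.nan, math.nan, math.nan, n, tuple(used_covs),
                                 f"fit failed: {exc}")
    return AssociationResult(
        outcome_id=outcome,
        predictor_id=predictor,
        model="logistic" if binary else "linear",
        slope=float(fit.params[predictor]),
        se=float(fit.bse[predictor]),
        p_value=float(fit.pvalues[predictor]),
        n=n,
        covariates=tuple(used_covs),
        warning=warn,
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    retained: bool = False
    n_pos: int = 0
    n_neg: int = 0
    warning: str = ""


def roc_youden(scores: Sequence[float], labels: Sequence[float]) -> ROCResult:
    """Youden-optimal operating point for a score where *higher is more
    adverse* (the orientation is fixed, never auto-flipped).

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores; a positive call is ``score > threshold``, so
    integer-valued scores always yield thresholds on the half-integer
    grid.  Ties in Youden's J are broken towards higher specificity, then
    the lower threshold.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    ok = ~(np.isnan(s) | np.isnan(y))
    s, y = s[ok], y[ok].astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC analysis")

    distinct = np.unique(s)
    if distinct.size == 1:
        warnings.warn("all scores identical; degenerate ROC")
        return ROCResult(distinct[0], 0.0, 1.0, 0.0, False, n_pos, n_neg, "degenerate")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in candidates:
        pos_call = s > thr
        sens = (pos_call & y).sum() / n_pos
        spec = (~pos_call & ~y).sum() / n_neg
        j = sens + spec - 1.0
        rank = (j, spec, -thr)
        if best is None or rank > best[0]:
            best = (rank, thr, sens, spec, j)
    _, thr, sens, spec, j = best
    return ROCResult(float(thr), float(sens), float(spec), float(j), n_pos=n_pos, n_neg=n_neg)


def retain_variables(
    roc_results: dict[str, ROCResult] | Iterable[tuple[str, ROCResult]],
    min_sensitivity: float = 0.60,
) -> list[str]:
    """Screening variables kept for the final case-control comparison:
    those whose Youden-optimal sensitivity is at least ``min_sensitivity``
    (boundary inclusive) for at least one associated outcome."""
    items = roc_results.items() if isinstance(roc_results, dict) else roc_results
    retained = []
    for name, res in items:
        res.retained = res.sensitivity >= min_sensitivity
        if res.retained and name not in retained:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# two-sample comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable_id: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: int
    p_value: float
    test: str = "pooled two-sample t"
    warning: str = ""


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2, variable_id: str = "") -> GroupComparison:
    """Pooled-variance Student t-test from group summary statistics.

    Reproduces a t-test on raw data exactly when the raw data have the
    given means/SDs, which makes printed summary tables re-checkable.
    Degenerate zero-variance inputs return p = 1 for equal means and a
    flagged p -> 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return GroupComparison(variable_id, m1, s1, n1, m2, s2, n2, 0.0, df, 1.0)
        return GroupComparison(variable_id, m1, s1, n1, m2, s2, n2, math.inf, df, 0.0,
                               warning="degenerate: zero variance, unequal means")
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(variable_id, m1, s1, n1, m2, s2, n2, float(t), df, float(p))


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
    groups: tuple = ("control", "case"),
) -> pd.DataFrame:
    """Per-variable pooled t comparison between two groups of a table
    (rows with a missing value are dropped per variable)."""
    g1 = data[data[group_col] == groups[0]]
    g2 = data[data[group_col] == groups[1]]
    rows = []
    for var in variables:
        if var not in data.columns:
            continue
        a = pd.to_numeric(g1[var], errors="coerce").dropna()
        b = pd.to_numeric(g2[var], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        cmp = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), var
        )
        rows.append(
            {
                "variable": var,
                f"{groups[0]}_mean": cmp.mean1, f"{groups[0]}_sd": cmp.sd1,
                f"{groups[0]}_n": cmp.n1,
                f"{groups[1]}_mean": cmp.mean2, f"{groups[1]}_sd": cmp.sd2,
                f"{groups[1]}_n": cmp.n2,
                "t": cmp.t, "df": cmp.df, "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)
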