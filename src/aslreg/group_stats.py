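"""ROI-wise group statistics: hypoperfusion/atrophy t-tests with Bonferroni
family-wise control, per-ROI severity regression, and demographic tests.

Two-tailed two-sample t-tests (pooled-variance by default, so df equals
n₁ + n₂ − 2; Welch available) are run independently in each parcel, with
Bonferroni correction over the number of tests (219 parcels by default)
at p_FWE < 0.05. The severity analysis regresses per-ROI mean CBF on a
clinical severity score with ordinary least squares and reports
uncorrected p < 0.05, since regional severity associations are weaker
than group contrasts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_FWE = 0.05


@dataclass
class ROITestResult:
    parcel: int
    t_statistic: float
    df: int
    p_raw: float
    p_bonferroni: float
    significant_fwe: bool
    direction: str  # lower_in_group1 | higher_in_group1


@dataclass
class SeverityRegressionResult:
    parcel: int
    slope: float
    intercept: float
    p_raw: float
    significant_uncorrected: bool


def _roi_wide(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Long (participant, parcel, value) -> wide participants x parcels."""
    return table.pivot(index="participant_id", columns="parcel", values=value_col)


def roi_group_ttest(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    n_tests: int = 219,
    equal_var: bool = True,
    alpha: float = ALPHA_FWE,
) -> list[ROITestResult]:
    """Per-parcel two-tailed two-sample t-tests with Bonferroni correction.

    ``values_a``/``values_b`` are wide tables (rows participants, columns
    parcel ids) of ROI mean CBF or ROI volume. A parcel missing in more
    than half of either group is skipped with a log entry. The same engine
    serves perfusion and atrophy contrasts.
    """
    results: list[ROITestResult] = []
    parcels = [c for c in values_a.columns if c in values_b.columns]
    for parcel in parcels:
        a = values_a[parcel].dropna().to_numpy(float)
        b = values_b[parcel].dropna().to_numpy(float)
        if len(a) < max(2, len(values_a) / 2) or len(b) < max(2, len(values_b) / 2):
            logger.info("parcel %s skipped: missing in >50%% of a group", parcel)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        df = len(a) + len(b) - 2 if equal_var else _welch_df(a, b)
        p_bonf = min(1.0, float(p) * n_tests)
        results.append(
            ROITestResult(
                parcel=int(parcel),
                t_statistic=float(t),
                df=int(df),
                p_raw=float(p),
                p_bonferroni=p_bonf,
                significant_fwe=bool(p_bonf < alpha),
                direction="lower_in_group1" if a.mean() < b.mean() else "higher_in_group1",
            )
        )
    return results


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def roi_results_frame(results: list[ROITestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def severity_regression(
    roi_cbf: pd.DataFrame,
    severity: pd.Series,
    alpha: float = 0.05,
) -> list[SeverityRegressionResult]:
    """OLS of per-ROI mean CBF on a severity score (CBF as response).

    ``roi_cbf`` is wide (participants x parcels); ``severity`` is indexed
    by participant id. Participants lacking a severity score are excluded.
    A negative slope is an inverse CBF–severity association.
    """
    sev = severity.dropna()
    common = roi_cbf.index.intersection(sev.index)
    if len(common) < 3:
        raise ValueError("need >= 3 participants with severity scores")
    sev = sev.loc[common].to_numpy(float)
    if np.var(sev) == 0:
        raise ValueError("severity has zero variance; regression undefined")
    design = sm.add_constant(sev)
    out: list[SeverityRegressionResult] = []
    for parcel in roi_cbf.columns:
        y = roi_cbf.loc[common, parcel].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        fit = sm.OLS(y[ok], design[ok]).fit()
        slope = float(fit.params[1])
        p = float(fit.pvalues[1])
        out.append(
            SeverityRegressionResult(
                parcel=int(parcel),
                slope=slope,
                intercept=float(fit.params[0]),
                p_raw=p,
                significant_uncorrected=bool(p < alpha),
            )
        )
    return out


def compare_demographics(
    manifest: pd.DataFrame,
    group_a: str,
    group_b: str,
    ordinal: tuple[str, ...] = ("age", "severity"),
    categorical: tuple[str, ...] = ("sex",),
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Between-group demographic tests: pooled t for ordinal variables
    (df = n₁ + n₂ − 2), chi-squared for categorical ones."""
    rows = []
    a = manifest[manifest["group"] == group_a]
    b = manifest[manifest["group"] == group_b]
    for col in ordinal:
        if col not in manifest.columns:
            continue
        x, y = a[col].dropna(), b[col].dropna()
        t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(t):
            t, p = 0.0, 1.0
        rows.append(
            {"variable": col, "test": "t", "statistic": float(t),
             "df": len(x) + len(y) - 2, "p_value": float(p)}
        )
    for col in categorical:
        if col not in manifest.columns:
            continue
        table = pd.crosstab(
            manifest.loc[manifest["group"].isin([group_a, group_b]), "group"],
            manifest.loc[manifest["group"].isin([group_a, group_b]), col],
        )
        if table.shape[1] < 2:  # all one category: no association testable
            rows.append({"variable": col, "test": "chi2", "statistic": 0.0,
                         "df": 0, "p_value": 1.0})
            continue
        chi2, p, df, _ = stats.chi2_contingency(
            table.to_numpy(), correction=continuity_correction
        )
        rows.append(
            {"variable": col, "test": "chi2", "statistic": float(chi2),
             "df": int(df), "p_value": float(p)}
        )
    return pd.DataFrame(rows)
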