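"""Regression layer: outcome ~ coating + day (+ interaction when it helps),
contrasts versus the matrigel reference at each day, and agreement statistics
between manual and automated counts.

Coating and day are categorical; the interaction is added only when a
partial F-test shows it significantly improves the fit (alpha = 0.05).
No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps

from .errors import DataError, FittingError

ALPHA = 0.05
_RSS_TOL = 1e-10


@dataclass
class RegressionFit:
    outcome: str
    formula: str
    interaction_included: bool
    excluded_days: list[int]
    reference: str
    coatings: list[str]
    days: list[int]
    coefficients: pd.DataFrame  # term, estimate, se
    contrasts: pd.DataFrame  # coating, day, estimate, se, p_value, significant
    interaction_p: float | None = None
    result: object = dc_field(default=None, repr=False)


@dataclass
class AgreementStats:
    pearson_r: float | None
    paired_t_p: float
    mean_difference: float
    duplicate_error: float | None = None


def _rss(res) -> float:
    return float(np.sum(res.resid**2))


def fit_outcome_model(
    table: pd.DataFrame,
    outcome: str,
    *,
    exclude_day1: bool = False,
    reference: str = "matrigel",
    alpha: float = ALPHA,
    compute_contrasts: bool = True,
) -> RegressionFit:
    """Fit the selected linear model for one outcome.

    Fits the additive and the interaction model by least squares and keeps
    the interaction only when the partial F-test on residual sums of squares
    is significant at ``alpha``. When ``exclude_day1``, day-1 rows are
    dropped before fitting (used for myotube number and the differentiation
    index, where the day-1 response is absent).
    """
    if outcome not in table.columns:
        raise FittingError(f"outcome {outcome!r} not in table")
    data = table.dropna(subset=[outcome]).copy()
    excluded_days: list[int] = []
    if exclude_day1:
        excluded_days = sorted(set(data["day"]) & {1})
        data = data[data["day"] != 1]

    coatings = sorted(data["coating"].unique())
    days = sorted(int(d) for d in data["day"].unique())
    if reference not in coatings:
        raise FittingError(f"reference coating {reference!r} absent from table")
    if len(coatings) < 2 or len(days) < 2:
        raise FittingError(
            f"need >= 2 coatings and >= 2 days, got {len(coatings)} coating(s), "
            f"{len(days)} day(s)"
        )

    base = f"Q('{outcome}') ~ C(coating, Treatment('{reference}')) + C(day)"
    inter = base + f" + C(coating, Treatment('{reference}')):C(day)"
    res_add = smf.ols(base, data=data).fit()
    if res_add.df_resid < 1:
        raise FittingError(f"additive model for {outcome!r} has no residual degrees of freedom")
    res_int = smf.ols(inter, data=data).fit()

    rss_add, rss_int = _rss(res_add), _rss(res_int)
    df_num = res_add.df_resid - res_int.df_resid
    scale = max(rss_add, 1.0)
    if df_num <= 0:
        include, p_int = False, None
    elif res_int.df_resid < 1:
        # saturated model is untestable; include only on a perfect-fit improvement
        include = rss_int < _RSS_TOL * scale and rss_add > _RSS_TOL * scale
        p_int = 0.0 if include else None
    elif rss_int < _RSS_TOL * scale:
        include = rss_add > _RSS_TOL * scale
        p_int = 0.0 if include else 1.0
    else:
        f_stat = ((rss_add - rss_int) / df_num) / (rss_int / res_int.df_resid)
        p_int = float(sps.f.sf(f_stat, df_num, res_int.df_resid))
        include = p_int < alpha

    res = res_int if include else res_add
    formula = inter if include else base

    se_vals = res.bse.values if res.df_resid >= 1 else np.zeros(len(res.params))
    coef = pd.DataFrame(
        {"term": res.params.index, "estimate": res.params.values, "se": se_vals}
    )
    contrasts = (
        _contrast_table(res, coatings, days, reference, alpha)
        if compute_contrasts
        else pd.DataFrame()
    )
    return RegressionFit(
        outcome=outcome,
        formula=formula,
        interaction_included=include,
        excluded_days=excluded_days,
        reference=reference,
        coatings=coatings,
        days=days,
        coefficients=coef,
        contrasts=contrasts,
        interaction_p=p_int,
        result=res,
    )


def _contrast_table(res, coatings, days, reference, alpha) -> pd.DataFrame:
    design_info = res.model.data.design_info
    rows = []
    for coating in coatings:
        for day in days:
            (x_c,) = build_design_matrices(
                [design_info], pd.DataFrame({"coating": [coating], "day": [day]})
            )
            (x_ref,) = build_design_matrices(
                [design_info], pd.DataFrame({"coating": [reference], "day": [day]})
            )
            diff = np.asarray(x_c)[0] - np.asarray(x_ref)[0]
            if coating == reference:
                est, se, p = 0.0, 0.0, 1.0
            elif res.df_resid < 1:
                # saturated fit: differences are exact, not estimated
                est = float(diff @ res.params)
                se = 0.0
                p = 0.0 if abs(est) > 1e-10 else 1.0
            else:
                tt = res.t_test(diff)
                est = float(np.squeeze(tt.effect))
                se = float(np.squeeze(tt.sd))
                p = float(np.squeeze(tt.pvalue))
                if se == 0 or not np.isfinite(p):
                    # perfect fit: the difference is exact, not estimated
                    p = 0.0 if abs(est) > 1e-10 else 1.0
            rows.append(
                {
                    "coating": coating,
                    "day": day,
                    "estimate": est,
                    "se": se,
                    "p_value": p,
                    "significant": bool(p < alpha) and coating != reference,
                }
            )
    return pd.DataFrame(rows)


def contrasts_vs_reference(fit: RegressionFit, days: list[int]) -> pd.DataFrame:
    """Model-estimated (coating - reference) differences at the given days."""
    missing = sorted(set(days) - set(fit.days))
    if missing:
        raise FittingError(f"days {missing} outside the modeled days {fit.days}")
    out = fit.contrasts[fit.contrasts["day"].isin(days)].reset_index(drop=True)
    return out


def validate_counts(
    manual: np.ndarray,
    automated: np.ndarray,
    duplicates: np.ndarray | None = None,
) -> AgreementStats:
    """Agreement between manual and automated counts.

    Pearson r (undefined when either vector is constant), a two-sided paired
    t-test on the differences (exact-constant differences are resolved in
    closed form), the signed mean of (manual - automated), and, when a second
    automated run is given, the SD of run-to-run differences as the duplicate
    measurement error.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape or manual.ndim != 1:
        raise DataError("manual and automated must be equal-length 1-D vectors")
    if len(manual) < 3:
        raise DataError("need at least 3 paired observations")

    if np.ptp(manual) == 0 or np.ptp(automated) == 0:
        r = None
    else:
        r = float(sps.pearsonr(manual, automated).statistic)

    diffs = manual - automated
    mean_diff = float(diffs.mean())
    if np.ptp(diffs) == 0:
        # zero-variance differences: t is infinite unless the shift is 0
        t_p = 1.0 if mean_diff == 0 else 0.0
    else:
        t_p = float(sps.ttest_rel(manual, automated).pvalue)

    dup_err = None
    if duplicates is not None:
        duplicates = np.asarray(duplicates, dtype=float)
        if duplicates.shape != automated.shape:
            raise DataError("duplicate run must match the automated vector's shape")
        dup_err = float(np.std(automated - duplicates, ddof=1))

    return AgreementStats(
        pearson_r=r, paired_t_p=t_p, mean_difference=mean_diff, duplicate_error=dup_err
    )
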