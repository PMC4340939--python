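"""Reconciliation of model-based and design-based population estimates.

Summing a year's abundance surface within a stratum (x2, pairs to
individuals) gives a model-based stratum estimate directly comparable to
the design-based strip-transect expansion.  Concordance is summarized by
regressing design on model estimates (slope ~ 1 and high r^2 indicate the
spatial model reproduces the survey's stratum totals), by standardized
residuals flagging strata the model persistently over-predicts, and by
yearly total trends with the design estimator's 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simdata import SurveyDesign
from .surfaces import AbundanceSurface
from .survey import PAIRS_TO_INDIVIDUALS, StratumEstimate


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float  # residual standard error (n-2 denominator)
    n: int


def model_based_stratum_estimate(
    surface: AbundanceSurface,
    design: SurveyDesign,
    stratum_id: int,
    year: int | None = None,
) -> StratumEstimate:
    """2 x the surface's pair total over cells inside the stratum."""
    st = design.stratum(stratum_id)
    g = surface.pairs
    if st.row_start >= g.nrows:
        raise ValueError(f"stratum {stratum_id} lies outside the grid")
    block = g.data[st.row_start : st.row_stop, :]
    valid = ~np.isclose(block, g.nodata) & ~np.isnan(block)
    total_pairs = float(block[valid].sum())
    if year is None:
        year = int(surface.label) if surface.label.isdigit() else -1
    return StratumEstimate(
        stratum_id=stratum_id,
        year=year,
        estimate=PAIRS_TO_INDIVIDUALS * total_pairs,
        sampled_area_km2=st.area_km2,
        stratum_area_km2=st.area_km2,
        se=float("nan"),
        method="model",
    )


def regress_estimates(model_estimates: np.ndarray, design_estimates: np.ndarray) -> RegressionResult:
    """OLS of design-based on model-based estimates.

    A slope near 1 with a near-zero intercept indicates the spatial model
    is an unbiased predictor of the survey's stratum estimates.
    """
    x = np.asarray(model_estimates, dtype=float)
    y = np.asarray(design_estimates, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 stratum-year pairs")
    if np.std(x) == 0:
        raise ValueError("constant model estimates: regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(fit.ssr / (len(x) - 2)))
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        residual_sd=resid_sd,
        n=len(x),
    )


def standardized_residuals(
    estimates: pd.DataFrame,
    regression: RegressionResult | None = None,
    flag_threshold: float = -2.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Standardized regression residuals by stratum-year, with flags.

    ``estimates`` needs columns stratum_id, year, model, design.  The
    residual is (design - fitted)/residual SD; a stratum is flagged when
    its standardized residual falls below the threshold in strictly more
    than half of the years (the model persistently over-predicts there).
    """
    req = {"stratum_id", "year", "model", "design"}
    if not req.issubset(estimates.columns):
        raise ValueError(f"estimates must have columns {sorted(req)}")
    if regression is None:
        regression = regress_estimates(estimates["model"].to_numpy(), estimates["design"].to_numpy())
    fitted = regression.intercept + regression.slope * estimates["model"].to_numpy()
    resid = estimates["design"].to_numpy() - fitted
    # an (almost) exact fit has no meaningful residual scale
    scale = max(1.0, float(np.abs(estimates["design"]).max()))
    if regression.residual_sd > 1e-9 * scale:
        std_resid = resid / regression.residual_sd
    else:
        std_resid = np.zeros_like(resid)
    out = estimates.copy()
    out["std_residual"] = std_resid
    n_years = out["year"].nunique()
    flags = []
    for stratum, grp in out.groupby("stratum_id"):
        if (grp["std_residual"] < flag_threshold).sum() > n_years / 2:
            flags.append(int(stratum))
    return out, sorted(flags)


def aggregate_trend_comparison(estimates: pd.DataFrame) -> pd.DataFrame:
    """Yearly totals across strata, percent difference, and CI overlap.

    ``estimates`` needs columns stratum_id, year, model, design and
    optionally design_se.  The design total's 95% CI combines stratum SEs
    as sqrt(sum SE^2); the indicator records whether the model total falls
    inside it (None when SEs are unavailable).
    """
    rows = []
    has_se = "design_se" in estimates.columns
    for year, grp in estimates.groupby("year"):
        model_total = float(grp["model"].sum())
        design_total = float(grp["design"].sum())
        pct = 100.0 * (model_total - design_total) / design_total
        row = {
            "year": year,
            "model_total": model_total,
            "design_total": design_total,
            "pct_difference": pct,
        }
        if has_se and grp["design_se"].notna().all():
            se = float(np.sqrt((grp["design_se"] ** 2).sum()))
            row["ci_low"] = design_total - 1.96 * se
            row["ci_high"] = design_total + 1.96 * se
            row["within_ci"] = bool(row["ci_low"] <= model_total <= row["ci_high"])
        else:
            row["ci_low"] = row["ci_high"] = float("nan")
            row["within_ci"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def pond_year_similarity(pond_totals: dict[int, float]) -> tuple[tuple[int, int], float]:
    """The pair of years with the most similar total pond counts.

    Scans all year pairs for the smallest absolute difference; ties go to
    the earliest pair.  Returns ``((year_i, year_j), difference)`` with
    year_i < year_j.
    """
    if len(pond_totals) < 2:
        raise ValueError("need at least 2 years of pond totals")
    years = sorted(pond_totals)
    best: tuple[int, int] | None = None
    best_diff = np.inf
    for i, yi in enumerate(years):
        for yj in years[i + 1 :]:
            diff = abs(pond_totals[yi] - pond_totals[yj])
            if diff < best_diff:
                best_diff = diff
                best = (yi, yj)
    return best, float(best_diff)
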