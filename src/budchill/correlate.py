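"""Expression-temperature correlation.

Per-timepoint mean expression is correlated (Pearson) with short-horizon
temperature covariates: the mean daily temperature on the sampling date and
the chill (CH, CP) or heat (GDH) accrued in a trailing window (default 14
days).  Correlations are reported pooled across cultivars and per cultivar;
pooling groups with different intercepts or slopes attenuates |r|, so both
groupings matter scientifically.  Ordinary least-squares slopes and
intercepts accompany every correlation, and a detection-threshold summary
(`expression_onset_temperature`) captures genes expressed only below some
temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionProfileMatrix
from .thermal import (
    HourlyTemperatureSeries,
    chill_portions,
    chilling_hours,
    growing_degree_hours,
    mean_daily_temperature,
    windowed_chill_sum,
)

__all__ = [
    "CorrelationError",
    "COVARIATE_NAMES",
    "build_covariates",
    "correlate",
    "fit_line_by_group",
    "correlation_matrix",
    "expression_onset_temperature",
]

COVARIATE_NAMES = ["mean_daily_temp", "ch_sum_14d", "cp_sum_14d", "gdh_sum_14d"]
POOLED = "pooled"


class CorrelationError(ValueError):
    pass


def build_covariates(
    series: HourlyTemperatureSeries,
    sampling_dates,
    window_days: int = 14,
    include_gdh: bool = True,
) -> pd.DataFrame:
    """Temperature covariates per sampling date.

    Columns: ``mean_daily_temp`` (degC on the sampling day), ``ch_sum_14d``,
    ``cp_sum_14d`` and optionally ``gdh_sum_14d`` (window sums over the
    trailing ``window_days``), plus a ``truncated`` flag for dates whose
    window begins before the series starts (those windows are computed on
    the available hours).
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(sampling_dates))).normalize()
    accs = {"ch": chilling_hours(series), "cp": chill_portions(series)}
    if include_gdh:
        accs["gdh"] = growing_degree_hours(series)
    rows = []
    for d in dates:
        if d < series.start.normalize() or d > series.end.normalize():
            raise CorrelationError(f"sampling date {d.date()} outside temperature series")
        window_start = d + pd.Timedelta(hours=23) - pd.Timedelta(days=window_days)
        row = {
            "date": d,
            "mean_daily_temp": mean_daily_temperature(series, d),
            "truncated": bool(window_start < series.start),
        }
        for name, acc in accs.items():
            row[f"{name}_sum_{window_days}d"] = windowed_chill_sum(acc, d, window_days)
        rows.append(row)
    return pd.DataFrame(rows).set_index("date")


def _long_expression(profiles: ExpressionProfileMatrix) -> pd.DataFrame:
    long = profiles.values.stack(["date", "cultivar"], future_stack=True).rename("expr")
    return long.reset_index().rename(columns={"level_0": "gene"})


def _pearson_row(gene, covariate, group, x, y) -> dict:
    base = {"gene": gene, "covariate": covariate, "group": group,
            "n": int(len(x)), "r": np.nan, "p": np.nan,
            "slope": np.nan, "intercept": np.nan, "reason": ""}
    if len(x) < 3:
        base["reason"] = "fewer than 3 pairs"
        return base
    if np.std(x) == 0 or np.std(y) == 0:
        base["reason"] = "zero variance"
        return base
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    base.update(r=float(r), p=float(p), slope=float(fit.slope),
                intercept=float(fit.intercept))
    return base


def correlate(
    profiles: ExpressionProfileMatrix,
    covariates: pd.DataFrame,
    grouping: str = "both",
    covariate_cols: list[str] | None = None,
    include_truncated: bool = False,
) -> pd.DataFrame:
    """Pearson r, two-sided p, n and OLS fit per gene x covariate x group.

    ``grouping`` is "pooled" (all (timepoint, cultivar) means together),
    "by_cultivar", or "both".  Missing expression cells are dropped
    pairwise.  Dates whose covariate window was truncated at the series
    start are excluded unless ``include_truncated``.  p-values are the
    two-sided t-transform of r; no multiple-testing correction is applied
    (a Benjamini-Hochberg column can be added downstream).
    """
    if grouping not in {"pooled", "by_cultivar", "both"}:
        raise CorrelationError(f"unknown grouping {grouping!r}")
    cov = covariates if include_truncated else covariates[~covariates["truncated"]]
    cols = covariate_cols or [c for c in cov.columns if c != "truncated"]
    expr = _long_expression(profiles)
    merged = expr.merge(cov[cols].reset_index(), on="date", how="inner")

    groups: list[tuple[str, pd.DataFrame]] = []
    if grouping in {"pooled", "both"}:
        groups.append((POOLED, merged))
    if grouping in {"by_cultivar", "both"}:
        groups.extend((str(c), g) for c, g in merged.groupby("cultivar"))

    rows = []
    for gname, gdf in groups:
        for (gene,), sub in gdf.groupby(["gene"]):
            for c in cols:
                pair = sub[[c, "expr"]].dropna()
                rows.append(
                    _pearson_row(gene, c, gname, pair[c].to_numpy(), pair["expr"].to_numpy())
                )
    return pd.DataFrame(rows)


def fit_line_by_group(
    profiles: ExpressionProfileMatrix,
    covariates: pd.DataFrame,
    gene: str,
    covariate: str,
    groups: list[str] | None = None,
    include_truncated: bool = False,
) -> pd.DataFrame:
    """Per-cultivar OLS of one gene's mean expression on one covariate.

    Returns one row per requested group (default: every cultivar present)
    with slope, intercept, r and n; when exactly two groups are reported,
    a ``slope_difference`` column (first minus second) is attached to the
    first row.
    """
    if gene not in profiles.values.index:
        raise CorrelationError(f"gene {gene!r} absent from profiles")
    cov = covariates if include_truncated else covariates[~covariates["truncated"]]
    expr = _long_expression(profiles)
    expr = expr[expr["gene"] == gene]
    merged = expr.merge(cov[[covariate]].reset_index(), on="date", how="inner")
    present = list(merged["cultivar"].unique())
    wanted = groups or sorted(present)
    rows = []
    for g in wanted:
        sub = merged[merged["cultivar"] == g][[covariate, "expr"]].dropna()
        if sub.empty:
            raise CorrelationError(f"group {g!r} absent for gene {gene!r}")
        rows.append(_pearson_row(gene, covariate, g, sub[covariate].to_numpy(),
                                 sub["expr"].to_numpy()))
    out = pd.DataFrame(rows)
    if len(wanted) == 2:
        out.loc[0, "slope_difference"] = out.loc[0, "slope"] - out.loc[1, "slope"]
    return out


def correlation_matrix(reports: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """Pivot correlation reports into genes x covariates matrices per group.

    Returns ``{group: {"r": ..., "p": ..., "n": ...}}``; undefined
    correlations stay NaN (missing), never 0.
    """
    if reports.empty:
        raise CorrelationError("no correlation reports to pivot")
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for group, sub in reports.groupby("group"):
        out[str(group)] = {
            stat: sub.pivot(index="gene", columns="covariate", values=stat)
            for stat in ("r", "p", "n")
        }
    return out


def expression_onset_temperature(
    profiles: ExpressionProfileMatrix,
    covariates: pd.DataFrame,
    gene: str,
    detection_floor: float = 0.0,
) -> dict:
    """Highest sampling-date mean daily temperature at which a gene is expressed.

    A timepoint counts as expressed when its (cultivar-pooled) mean relative
    expression exceeds ``detection_floor``.  When the gene is expressed at
    every timepoint the overall maximum is returned flagged "no contrast";
    a never-expressed gene yields a missing value with reason.
    """
    if gene not in profiles.values.index:
        raise CorrelationError(f"gene {gene!r} absent from profiles")
    expr = profiles.values.loc[gene].groupby(level="date").mean()
    temps = covariates["mean_daily_temp"]
    joined = pd.concat([expr.rename("expr"), temps], axis=1, join="inner").dropna()
    expressed = joined[joined["expr"] > detection_floor]
    if expressed.empty:
        return {"gene": gene, "onset_temp": np.nan, "reason": "never expressed"}
    result = {"gene": gene, "onset_temp": float(expressed["mean_daily_temp"].max()),
              "reason": ""}
    if len(expressed) == len(joined):
        result["reason"] = "no contrast: expressed at every timepoint"
    return result
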