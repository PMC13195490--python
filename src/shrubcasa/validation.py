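"""Remote-sensing vs field validation, NEP trend maps, age projection.

Three outputs close the loop between the raster pipeline and the plot
accounting: (1) paired regression statistics between estimated (remote
sensing) and measured (field) carbon densities; (2) per-pixel linear NEP
trends over years with significance-based increase/stable/decrease
classes; (3) a year-by-year projection of pool carbon densities against
stand age, with baseline and first-year machinery leakage deducted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fieldcarbon import CarbonPoolLedger
from .nep import gc_m2_to_tco2_ha
from .raster import aligned

log = logging.getLogger(__name__)


@dataclass
class ValidationStats:
    """OLS of estimated on measured plus accuracy about the 1:1 line.

    ``rmse`` is the root mean squared (estimated - measured) difference —
    scatter about the 1:1 line; ``rmse_fitted`` is the residual RMSE about
    the fitted regression line.
    """

    n: int
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    rmse_fitted: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "pearson_r", "slope", "intercept", "r_squared",
                 "rmse", "rmse_fitted")}


def paired_validation(estimated, measured) -> ValidationStats:
    """Validation statistics from paired density lists (tCO2 ha-1)."""
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.ndim != 1:
        raise ValueError("estimated and measured must be equal-length 1-D")
    n = est.size
    if n < 3:
        raise ValueError("need at least 3 plot pairs")
    sxx = float(np.sum((mea - mea.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in measured values")
    sxy = float(np.sum((mea - mea.mean()) * (est - est.mean())))
    slope = sxy / sxx
    intercept = float(est.mean() - slope * mea.mean())
    pred = intercept + slope * mea
    syy = float(np.sum((est - est.mean()) ** 2))
    if syy == 0:
        r = 0.0
        r2 = 0.0
    else:
        r = sxy / np.sqrt(sxx * syy)
        r2 = 1.0 - float(np.sum((est - pred) ** 2)) / syy
    rmse = float(np.sqrt(np.mean((est - mea) ** 2)))
    rmse_fit = float(np.sqrt(np.mean((est - pred) ** 2)))
    return ValidationStats(n=n, pearson_r=float(r), slope=float(slope),
                           intercept=intercept, r_squared=float(r2),
                           rmse=rmse, rmse_fitted=rmse_fit)


class TrendClass:
    DECREASE = -1
    STABLE = 0
    INCREASE = 1


def pixel_trend(annual_nep: dict[int, np.ma.MaskedArray], alpha: float = 0.05):
    """Per-cell OLS slope of NEP on year with a two-sided t-test.

    Cells with slope > 0 and p < alpha are INCREASE, slope < 0 and
    p < alpha DECREASE, otherwise STABLE.  Returns (slope grid, p grid,
    class grid, fractions dict); fractions are over unmasked cells and
    sum to 1.
    """
    years = sorted(annual_nep)
    if len(years) < 4:
        raise ValueError("need at least 4 years for a trend")
    yr = np.asarray(years, dtype=float)
    data = np.ma.stack([np.ma.asarray(annual_nep[y], dtype=float)
                        for y in years])
    n = len(years)
    ybar = yr.mean()
    sxx = float(np.sum((yr - ybar) ** 2))
    dev = (yr - ybar)[:, None, None]
    mean = data.mean(axis=0)
    slope = (data * dev).sum(axis=0) / sxx
    pred = mean + slope * dev
    sse = ((data - pred) ** 2).sum(axis=0)
    dof = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.ma.sqrt(sse / dof / sxx)
        tstat = np.ma.where(se == 0,
                            np.sign(slope) * np.inf,
                            slope / np.ma.where(se == 0, 1.0, se))
    p = np.ma.masked_array(
        2.0 * stats.t.sf(np.abs(np.ma.filled(tstat, 0.0)), dof),
        mask=np.ma.getmaskarray(slope))
    cls = np.ma.where(
        (p < alpha) & (slope > 0), TrendClass.INCREASE,
        np.ma.where((p < alpha) & (slope < 0), TrendClass.DECREASE,
                    TrendClass.STABLE))
    valid = ~np.ma.getmaskarray(slope)
    total = int(valid.sum())
    fracs = {
        "increase": float(np.sum(np.ma.filled(cls, 99)[valid] == 1)) / total,
        "decrease": float(np.sum(np.ma.filled(cls, 99)[valid] == -1)) / total,
        "stable": float(np.sum(np.ma.filled(cls, 99)[valid] == 0)) / total,
    }
    log.info("pixel trend over %d years: %.1f%% increase, %.1f%% decrease, "
             "%.1f%% stable", n, 100 * fracs["increase"],
             100 * fracs["decrease"], 100 * fracs["stable"])
    return slope, p, cls, fracs


def stratum_timeseries(annual_nep: dict[int, np.ma.MaskedArray], site_types):
    """Yearly zonal NEP means per site type plus the all-area linear trend.

    Returns (DataFrame year x site-type means incl. "ALL", trend
    coefficient of the all-area mean on year).
    """
    from .terrain import SiteType, zonal_summary

    years = sorted(annual_nep)
    zones = np.ma.asarray(site_types)
    rows = []
    for y in years:
        grid = np.ma.asarray(annual_nep[y], dtype=float)
        aligned(grid, zones)
        summ = zonal_summary(grid, zones)
        row = {"year": y, "ALL": float(grid.mean())}
        for st in SiteType:
            row[st.name] = summ[int(st)]["mean"]
        rows.append(row)
    df = pd.DataFrame(rows)
    coef = float(np.polyfit(df["year"].to_numpy(float),
                            df["ALL"].to_numpy(float), 1)[0])
    return df, coef


@dataclass
class ProjectionTable:
    """Per-age-year pool densities and cumulative net sequestration."""

    table: pd.DataFrame           # columns: age, above..soil, gross_tco2_ha,
                                  # net_tco2_ha
    baseline_tco2_ha: float
    leakage_tco2_ha: float
    first_net_positive_year: int | None


def _monotone_linear_fit(ages, values):
    """OLS line with the slope floored at zero (pools cannot shrink with age)."""
    slope, intercept = np.polyfit(ages, values, 1)
    if slope < 0:
        slope, intercept = 0.0, float(np.mean(values))
    return float(slope), float(intercept)


def project_by_age(ledgers: list[CarbonPoolLedger], max_age: int,
                   leakage: float, baseline_tco2_ha: float = 0.0) -> ProjectionTable:
    """Year-by-year pool projection from age 1 to ``max_age``.

    Above/below pools: mean ledger density per observed age, regressed
    linearly on age with a monotone (non-negative slope) constraint.
    Herb and soil pools: plain OLS linear-in-age models (may decline).
    Litter: the cross-age mean, a conservative constant.  Gross density is
    the pool sum per age; the net curve subtracts the grassland baseline
    and applies machinery leakage at year 1.  Projected pool stocks are
    floored at zero.
    """
    df = pd.DataFrame([l.as_dict() for l in ledgers])
    ages_obs = np.sort(df["age_yr"].unique())
    if len(ages_obs) < 3:
        raise ValueError("need ledgers spanning at least 3 distinct ages")
    by_age = df.groupby("age_yr")[["above", "below", "herb", "litter",
                                   "soil"]].mean()
    a = by_age.index.to_numpy(float)

    models = {}
    for pool in ("above", "below"):
        models[pool] = _monotone_linear_fit(a, by_age[pool].to_numpy(float))
    for pool in ("herb", "soil"):
        s, i = np.polyfit(a, by_age[pool].to_numpy(float), 1)
        models[pool] = (float(s), float(i))
    litter_mean = float(by_age["litter"].mean())

    rows = []
    first_pos = None
    for age in range(1, max_age + 1):
        pools = {p: max(models[p][0] * age + models[p][1], 0.0)
                 for p in ("above", "below", "herb", "soil")}
        pools["litter"] = max(litter_mean, 0.0)
        gross_gc = sum(pools.values())
        gross = float(gc_m2_to_tco2_ha(gross_gc))
        net = gross - baseline_tco2_ha - leakage
        if first_pos is None and net > 0:
            first_pos = age
        rows.append({"age": age, **pools, "gross_tco2_ha": gross,
                     "net_tco2_ha": net})
    table = pd.DataFrame(rows)
    log.info("projection to age %d: gross %.1f tCO2/ha, net %.1f tCO2/ha, "
             "first net-positive year %s", max_age,
             table["gross_tco2_ha"].iloc[-1], table["net_tco2_ha"].iloc[-1],
             first_pos)
    return ProjectionTable(table=table, baseline_tco2_ha=baseline_tco2_ha,
                           leakage_tco2_ha=leakage,
                           first_net_positive_year=first_pos)


def leakage_share(leakage: float, cumulative_gross: float) -> float:
    """Leakage as a percentage of cumulative gross sequestration."""
    if cumulative_gross <= 0:
        raise ValueError("cumulative gross must be positive")
    return 100.0 * leakage / cumulative_gross
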