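"""Soil respiration, heterotrophic respiration and net ecosystem productivity.

NEP = NPP - Rh per cell and month; positive NEP is a carbon sink, negative
a source (the sign is preserved).  Total soil respiration follows an
exponential temperature response with precipitation half-saturation,

    Rs = f * exp(b * Ta) * P / (k + P)        (P in cm month-1)

and its heterotrophic component comes from the empirical log-log relation
ln Rh = 0.22 + 0.87 ln Rs.  Multi-year cumulative NEP is the pipeline's
net carbon-sequestration-density proxy (gC m-2), with a units bridge to
tCO2 ha-1 for reporting.

Callers supply precipitation in mm everywhere; the mm -> cm conversion the
respiration model needs is owned here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .casa import NppLayer
from .raster import MonthlyRasterStack, aligned, parse_month

log = logging.getLogger(__name__)

#: gC m-2  ->  tCO2 ha-1:  (44/12) molecular ratio, 1 g m-2 = 0.01 t ha-1
_GC_M2_TO_TCO2_HA = (44.0 / 12.0) * 0.01


@dataclass(frozen=True)
class RespirationParams:
    """Respiration constants.

    b : temperature sensitivity of soil respiration (degC-1).
    f : saturation respiration scale (gC m-2 month-1).
    k : precipitation half-saturation constant (cm).
    rh_intercept / rh_slope : coefficients of ln Rh = a + b ln Rs.
    """

    b: float = 0.05452
    f: float = 1.250
    k: float = 4.259
    rh_intercept: float = 0.22
    rh_slope: float = 0.87

    def __post_init__(self) -> None:
        if self.f <= 0 or self.k <= 0:
            raise ValueError("f and k must be positive")
        if self.rh_slope <= 0:
            raise ValueError("rh_slope must be positive")


@dataclass
class NepLayer:
    nep: np.ma.MaskedArray
    rh: np.ma.MaskedArray
    rs: np.ma.MaskedArray | None = None
    month: str = ""


def soil_respiration(ta, p_mm, params: RespirationParams = RespirationParams()):
    """Monthly total soil respiration Rs (gC m-2 month-1).

    ``p_mm`` is monthly precipitation in mm; it is converted to the cm the
    model expects.  Rs = 0 where P = 0.
    """
    ta = np.ma.asarray(ta, dtype=float)
    p_mm = np.ma.asarray(p_mm, dtype=float)
    if np.ma.any(p_mm < 0):
        raise ValueError("precipitation must be non-negative")
    p_cm = p_mm / 10.0
    return params.f * np.ma.exp(params.b * ta) * (p_cm / (params.k + p_cm))


def heterotrophic_respiration(rs, params: RespirationParams = RespirationParams()):
    """Rh = exp(intercept) * Rs^slope, with Rh = 0 at Rs = 0 (continuous limit)."""
    rs = np.ma.asarray(rs, dtype=float)
    if np.ma.any(rs < 0):
        raise ValueError("soil respiration must be non-negative")
    safe = np.ma.where(rs == 0, 1.0, rs)
    rh = np.exp(params.rh_intercept) * np.ma.power(safe, params.rh_slope)
    return np.ma.where(rs == 0, 0.0, rh)


def compute_nep(npp, rh, month: str = "") -> NepLayer:
    """NEP = NPP - Rh per cell; negative values (carbon source) preserved.

    ``npp`` may be an :class:`~shrubcasa.casa.NppLayer` or a bare grid.
    """
    grid = npp.npp if isinstance(npp, NppLayer) else np.ma.asarray(npp, dtype=float)
    rh = np.ma.asarray(rh, dtype=float)
    aligned(grid, rh)
    return NepLayer(nep=grid - rh, rh=rh, month=month)


def compute_nep_stack(
    npp: MonthlyRasterStack,
    temp: MonthlyRasterStack,
    precip_mm: MonthlyRasterStack,
    params: RespirationParams = RespirationParams(),
) -> MonthlyRasterStack:
    """Monthly NEP stack from NPP and climate stacks sharing one month range."""
    if temp.months != npp.months or precip_mm.months != npp.months:
        raise ValueError("input stacks cover different month ranges")
    rs = soil_respiration(temp.data, precip_mm.data, params)
    rh = heterotrophic_respiration(rs, params)
    nep = npp.data - rh
    log.info(
        "NEP: %d months, b=%g f=%g k=%g; mean monthly Rh %.3f gC m-2",
        len(npp.months), params.b, params.f, params.k, float(rh.mean()),
    )
    return MonthlyRasterStack(nep, list(npp.months), npp.meta)


def cumulative_nep(monthly_neps: MonthlyRasterStack, period: tuple[int, int]):
    """Per-cell sum of monthly NEP over [start_year, end_year] inclusive.

    Requires a gap-free monthly record over the period; any cell masked in
    any month is masked in the output.  Returns (grid, month_count).
    """
    y0, y1 = period
    wanted = [f"{y:04d}-{m:02d}" for y in range(y0, y1 + 1) for m in range(1, 13)]
    missing = [m for m in wanted if m not in monthly_neps.months]
    if missing:
        more = f" (and {len(missing) - 1} more)" if len(missing) > 1 else ""
        raise ValueError(f"gap in monthly NEP record: missing {missing[0]}{more}")
    idx = [monthly_neps.months.index(m) for m in wanted]
    data = monthly_neps.data[idx]
    total = data.sum(axis=0)
    # propagate mask: a cell masked in any month is unusable in the sum
    anymask = np.ma.getmaskarray(data).any(axis=0)
    total = np.ma.masked_array(np.ma.filled(total, 0.0), mask=anymask)
    return total, len(wanted)


def gc_m2_to_tco2_ha(density):
    """gC m-2 -> tCO2 ha-1 (multiply by 44/12 and 0.01)."""
    return np.multiply(density, _GC_M2_TO_TCO2_HA)


def tco2_ha_to_gc_m2(density):
    """Inverse of :func:`gc_m2_to_tco2_ha`."""
    return np.divide(density, _GC_M2_TO_TCO2_HA)
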