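"""Monthly CASA light-use-efficiency NPP.

The Carnegie-Ames-Stanford Approach computes net primary productivity per
pixel and month as absorbed photosynthetically active radiation (APAR)
times an actual light-use efficiency, where the efficiency is a maximum
(unstressed) value down-regulated by two temperature stress factors and a
water stress factor:

    NPP(x,t)  = APAR(x,t) * eps(x,t)
    APAR(x,t) = SOL(x,t) * FPAR(x,t) * par_fraction
    eps(x,t)  = T1 * T2(x,t) * W(x,t) * eps_max

FPAR is a linear stretch of NDVI between fixed theoretical shrubland
bounds; the water stress factor is driven by the ratio of actual to
potential evapotranspiration.  Defaults are shrubland-specific literature
values; all are overridable through :class:`CasaParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import GridMeta, MonthlyRasterStack, aligned

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CasaParams:
    """CASA constants with their documented legal ranges.

    ndvi_max / ndvi_min : theoretical shrubland NDVI bounds (not taken from
        the observed NDVI range).
    fpar_max / fpar_min : vegetation-independent FPAR bounds.
    epsilon_max : maximum light-use efficiency, gC per MJ APAR.
    t_opt : optimum growth temperature, degC, uniform over the area.
    par_fraction : share of total solar radiation usable as PAR.
    """

    ndvi_max: float = 0.636
    ndvi_min: float = 0.023
    fpar_max: float = 0.95
    fpar_min: float = 0.001
    epsilon_max: float = 0.429
    t_opt: float = 22.0
    par_fraction: float = 0.48

    def __post_init__(self) -> None:
        if not self.ndvi_min < self.ndvi_max:
            raise ValueError("ndvi_min must lie below ndvi_max")
        if not 0 <= self.fpar_min < self.fpar_max:
            raise ValueError("fpar_min must lie in [0, fpar_max)")
        if not self.fpar_max <= 1:
            raise ValueError("fpar_max must lie in (0,1]")
        if not self.epsilon_max > 0:
            raise ValueError("epsilon_max must be positive")
        if not 0 < self.par_fraction < 1:
            raise ValueError("par_fraction must lie in (0,1)")


@dataclass
class StressFactors:
    """Diagnostic light-use-efficiency down-regulation factors."""

    t1: float
    t2: np.ma.MaskedArray
    w: np.ma.MaskedArray


@dataclass
class NppLayer:
    """Monthly NPP with its APAR/FPAR/stress diagnostics."""

    npp: np.ma.MaskedArray      # gC m-2 month-1
    apar: np.ma.MaskedArray     # MJ m-2 month-1
    fpar: np.ma.MaskedArray
    stress: StressFactors
    month: str
    meta: GridMeta | None = None


def compute_fpar(ndvi, params: CasaParams = CasaParams()) -> np.ma.MaskedArray:
    """Linear NDVI -> FPAR stretch, clamped to [fpar_min, fpar_max].

    The NDVI bounds are theoretical, so observed NDVI outside them maps to
    the boundary FPAR rather than extrapolating.
    """
    ndvi = np.ma.asarray(ndvi, dtype=float)
    frac = (ndvi - params.ndvi_min) / (params.ndvi_max - params.ndvi_min)
    fpar = frac * (params.fpar_max - params.fpar_min) + params.fpar_min
    return np.ma.clip(fpar, params.fpar_min, params.fpar_max)


def compute_apar(solar, fpar, params: CasaParams = CasaParams()) -> np.ma.MaskedArray:
    """APAR = SOL * FPAR * par_fraction (MJ m-2)."""
    solar = np.ma.asarray(solar, dtype=float)
    if np.ma.any(solar < 0):
        raise ValueError("solar radiation must be non-negative")
    return solar * np.ma.asarray(fpar, dtype=float) * params.par_fraction


def temp_stress_low(params: CasaParams = CasaParams()) -> float:
    """Low-temperature stress T1 = 0.8 + 0.02 Topt - 0.0005 Topt^2.

    Uniform across cells and months because Topt is a single constant.
    """
    t = params.t_opt
    return 0.8 + 0.02 * t - 0.0005 * t * t


def temp_stress_high(temp, params: CasaParams = CasaParams()) -> np.ma.MaskedArray:
    """High-temperature stress T2, a product of two logistic terms in T."""
    t = np.ma.asarray(temp, dtype=float)
    topt = params.t_opt
    first = 1.184 / (1.0 + np.ma.exp(0.2 * (topt - 10.0 - t)))
    second = 1.0 / (1.0 + np.ma.exp(0.3 * (-topt - 10.0 + t)))
    return first * second


def actual_et(p, rn) -> np.ma.MaskedArray:
    """Actual evapotranspiration from precipitation and net radiation.

    E = P*Rn*(P^2 + Rn^2 + P*Rn) / ((P + Rn)*(P^2 + Rn^2)), with E = 0 at
    the degenerate P + Rn = 0 or P = Rn = 0 cells.
    """
    p = np.ma.asarray(p, dtype=float)
    rn = np.ma.asarray(rn, dtype=float)
    if np.ma.any(p < 0):
        raise ValueError("precipitation must be non-negative")
    num = p * rn * (p * p + rn * rn + p * rn)
    den = (p + rn) * (p * p + rn * rn)
    safe = np.ma.where(den == 0, 1.0, den)
    return np.ma.where(den == 0, 0.0, num / safe)


def potential_et(temp, rn) -> np.ma.MaskedArray:
    """Potential evapotranspiration Ep = 0.0023 (T + 17.8) Rn * 30, floored at 0."""
    t = np.ma.asarray(temp, dtype=float)
    rn = np.ma.asarray(rn, dtype=float)
    if np.ma.any(rn < 0):
        raise ValueError("net radiation must be non-negative")
    ep = 0.0023 * (t + 17.8) * rn * 30.0
    return np.ma.maximum(ep, 0.0)


def water_stress(e, ep) -> np.ma.MaskedArray:
    """W = 0.5 + 0.5 * clamp(E/Ep, 0, 1); W = 0.5 (maximum stress) at Ep = 0."""
    e = np.ma.asarray(e, dtype=float)
    ep = np.ma.asarray(ep, dtype=float)
    safe = np.ma.where(ep == 0, 1.0, ep)
    with np.errstate(over="ignore"):
        # E/Ep can overflow for denormal Ep; any overflow clamps to 1 anyway
        ratio = np.ma.where(ep == 0, 0.0, np.ma.minimum(e, safe) / safe)
    return 0.5 + 0.5 * np.ma.clip(ratio, 0.0, 1.0)


def compute_npp_month(
    ndvi, solar, temp, p, rn,
    params: CasaParams = CasaParams(),
    month: str = "",
    meta: GridMeta | None = None,
) -> NppLayer:
    """One month of CASA NPP from co-registered grids (all same shape).

    Precipitation and net radiation feed the water-stress branch; units are
    mm month-1 and MJ m-2 month-1 respectively.
    """
    aligned(ndvi, solar, temp, p, rn)
    fpar = compute_fpar(ndvi, params)
    apar = compute_apar(solar, fpar, params)
    t1 = temp_stress_low(params)
    t2 = temp_stress_high(temp, params)
    e = actual_et(p, rn)
    ep = potential_et(temp, rn)
    w = water_stress(e, ep)
    eps = t1 * t2 * w * params.epsilon_max
    npp = apar * eps
    return NppLayer(npp=npp, apar=apar, fpar=fpar,
                    stress=StressFactors(t1=t1, t2=t2, w=w),
                    month=month, meta=meta)


def compute_npp_stack(
    ndvi: MonthlyRasterStack,
    solar: MonthlyRasterStack,
    temp: MonthlyRasterStack,
    precip: MonthlyRasterStack,
    rnet: MonthlyRasterStack,
    params: CasaParams = CasaParams(),
) -> MonthlyRasterStack:
    """Monthly NPP stack over the months shared by all five input stacks."""
    stacks = (ndvi, solar, temp, precip, rnet)
    months = ndvi.months
    for s in stacks[1:]:
        if s.months != months:
            raise ValueError("input stacks cover different month ranges")
        if not s.meta.same_grid(ndvi.meta):
            raise ValueError("input stacks have mismatched grids")
    log.info(
        "CASA NPP: %d months, eps_max=%g, Topt=%g, NDVI bounds [%g, %g]",
        len(months), params.epsilon_max, params.t_opt,
        params.ndvi_min, params.ndvi_max,
    )
    layers = [
        compute_npp_month(
            ndvi.data[i], solar.data[i], temp.data[i],
            precip.data[i], rnet.data[i], params, month=m, meta=ndvi.meta,
        ).npp
        for i, m in enumerate(months)
    ]
    return MonthlyRasterStack(np.ma.stack(layers), list(months), ndvi.meta)


def annual_sum(stack: MonthlyRasterStack) -> dict[int, np.ma.MaskedArray]:
    """Per-year sum of a monthly stack (annual NPP or NEP)."""
    from .raster import parse_month

    out: dict[int, np.ma.MaskedArray] = {}
    years = sorted({parse_month(m)[0] for m in stack.months})
    for y in years:
        idx = [i for i, m in enumerate(stack.months) if parse_month(m)[0] == y]
        out[y] = stack.data[idx].sum(axis=0)
    return out
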