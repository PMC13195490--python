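"""DEM-derived terrain strata: slope/aspect, site types, NDVI cover classes.

Site types follow the operational watershed rule set: gully bottoms are
low-slope cells (slope < 5 deg, aspect irrelevant); shady and sunny slopes
are 5-25 deg cells split by aspect (north-facing halves shady,
south-facing sunny); steeper cells are left unclassified.  Vegetation
cover classes come from exact Jenks natural-breaks optimisation of NDVI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .raster import aligned

log = logging.getLogger(__name__)


class SiteType(IntEnum):
    UNCLASSIFIED = 0
    SHADY_SLOPE = 1
    SUNNY_SLOPE = 2
    GULLY_BOTTOM = 3


def slope_aspect(dem, cell_size: float):
    """Horn 3x3 finite-difference slope (deg) and aspect (deg CW from north).

    Border cells fall back to one-sided differences via edge replication.
    Aspect is the downslope direction in [0, 360) and is masked where the
    slope is zero (undefined direction).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    z = np.ma.asarray(dem, dtype=float)
    filled = np.ma.filled(z, np.nan)
    zp = np.pad(filled, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    # x east (columns increasing), geographic y north (rows decreasing)
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dzdy_north = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy_north)))
    # downslope direction = -(gradient); atan2(east, north) CW from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy_north)) % 360.0
    slope = np.ma.masked_invalid(slope)
    aspect = np.ma.masked_invalid(aspect)
    aspect = np.ma.masked_where(slope == 0, aspect)
    return slope, aspect


def classify_site(slope, aspect) -> np.ma.MaskedArray:
    """Exhaustive, mutually exclusive site-type labels per cell.

    slope < 5         -> GULLY_BOTTOM
    5 <= slope <= 25  -> SHADY_SLOPE for aspect in [0,90) u [270,360),
                         SUNNY_SLOPE for aspect in [90,270)
    slope > 25        -> UNCLASSIFIED
    """
    slope = np.ma.asarray(slope, dtype=float)
    aspect = np.ma.asarray(aspect, dtype=float)
    aligned(slope, aspect)
    out = np.full(slope.shape, SiteType.UNCLASSIFIED, dtype=np.int16)
    gully = slope < 5.0
    on_slope = (slope >= 5.0) & (slope <= 25.0)
    asp = np.ma.filled(aspect % 360.0, 0.0)
    shady = on_slope & ((asp < 90.0) | (asp >= 270.0))
    sunny = on_slope & (asp >= 90.0) & (asp < 270.0)
    out[np.ma.filled(gully, False)] = SiteType.GULLY_BOTTOM
    out[np.ma.filled(shady, False)] = SiteType.SHADY_SLOPE
    out[np.ma.filled(sunny, False)] = SiteType.SUNNY_SLOPE
    return np.ma.masked_array(out, mask=np.ma.getmaskarray(slope))


@dataclass
class CoverClass:
    """Jenks natural-breaks classification of a 1-D sample."""

    breaks: list[float]          # k-1 upper-bound break values (sorted)
    k: int

    def assign(self, values) -> np.ndarray:
        """1-based class index per value (class i: value <= breaks[i-1])."""
        v = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.breaks), v, side="left") + 1


def jenks_breaks(values, k: int) -> CoverClass:
    """Exact Jenks natural breaks by dynamic programming.

    Minimises the total within-class sum of squared deviations over all
    partitions of the sorted sample into ``k`` contiguous classes.  Ties
    are broken toward the smaller upper class (later break positions).
    Breaks are reported as the largest member of each lower class.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    distinct = np.unique(v).size
    if k < 1:
        raise ValueError("k must be >= 1")
    if distinct < k:
        raise ValueError(f"need at least {k} distinct values, got {distinct}")
    # prefix sums for O(1) within-class SSD of v[i:j]
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        m = j - i
        return s2 - s * s / m

    INF = float("inf")
    # cost[c][j]: best total SSD splitting v[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                if cost[c - 1][i] == INF:
                    continue
                t = cost[c - 1][i] + ssd(i, j)
                # <= prefers the larger i: later break, smaller upper class
                if t <= best:
                    best, arg = t, i
            cost[c][j] = best
            back[c][j] = arg
    cuts = []
    j = n
    for c in range(k, 0, -1):
        i = back[c][j]
        cuts.append(i)
        j = i
    cuts = sorted(cuts)[1:]  # drop the leading 0
    breaks = [float(v[i - 1]) for i in cuts]
    return CoverClass(breaks=breaks, k=k)


def zonal_summary(value_grid, zones):
    """Mean, count and (population) std of unmasked cells per zone label.

    Returns ``{label: {"mean", "count", "std"}}`` for every label present
    in ``zones`` plus every :class:`SiteType`; empty zones report count 0
    and NaN statistics.
    """
    values = np.ma.asarray(value_grid, dtype=float)
    zones = np.ma.asarray(zones)
    aligned(values, zones)
    labels = sorted(set(int(z) for z in np.ma.compressed(zones))
                    | {int(s) for s in SiteType})
    out = {}
    vmask = np.ma.getmaskarray(values) | np.ma.getmaskarray(zones)
    zfill = np.ma.filled(zones, -1)
    for lab in labels:
        sel = (zfill == lab) & ~vmask
        n = int(sel.sum())
        if n == 0:
            out[lab] = {"mean": float("nan"), "count": 0, "std": float("nan")}
        else:
            vals = np.ma.filled(values, np.nan)[sel]
            out[lab] = {"mean": float(vals.mean()), "count": n,
                        "std": float(vals.std())}
    return out
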