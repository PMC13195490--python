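"""Synthetic semi-arid watershed: climate/NDVI rasters, DEM, plot surveys.

Every downstream stage of the pipeline is testable against known ground
truth generated here.  The defaults emulate the study system the package
targets: a small Ordos-plateau-style watershed (continental semi-arid
climate, summer-concentrated rainfall, elevation 900-1000 m) planted with
sea buckthorn, surveyed with a stratified plot design over stand ages
5-10 years and three terrain site types (shady slope, sunny slope, gully
bottom), with two 5 m x 5 m shrub quadrats, four 1 m x 1 m herb/litter
subplots and three soil sampling points per plot, plus grassland control
subplots/soil under comparable conditions.

Soil bulk density and organic carbon means per stand age and depth layer
follow the surveyed stand values; woody pool means are anchored so the
net (baseline-subtracted) densities reproduce the reported stand-age
pattern.  All generators are pure functions of (spec, seed): one global
seed is split into independent substreams per product, so adding one
generator never perturbs another's draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fieldcarbon import (
    SOIL_LAYERS,
    CarbonFractions,
    CarbonPoolLedger,
    DEFAULT_LEAKAGE_TCO2_HA,
)
from .raster import GridMeta, MonthlyRasterStack

log = logging.getLogger(__name__)

#: monthly share of annual precipitation (summer-concentrated, sums to 1)
PRECIP_MONTHLY_FRACTION = np.array(
    [0.01, 0.01, 0.02, 0.04, 0.07, 0.12, 0.22, 0.24, 0.14, 0.08, 0.03, 0.02]
)

#: surveyed stand soil means per age: {age: ((BD per layer), (SOC per layer))}
#: layers ordered 0-10, 10-20, 20-50 cm; BD g cm-3, SOC g kg-1
SOIL_TRUTH = {
    5: ((1.18, 1.26, 1.24), (3.04, 2.30, 2.06)),
    6: ((1.26, 1.24, 1.28), (3.76, 2.22, 2.06)),
    7: ((1.21, 1.26, 1.16), (3.12, 1.92, 2.08)),
    8: ((1.27, 1.42, 1.31), (3.48, 2.56, 2.69)),
    9: ((1.24, 1.26, 1.16), (4.44, 3.37, 4.52)),
    10: ((1.25, 1.29, 1.25), (6.20, 4.49, 4.46)),
}

#: grassland control soil (age-invariant): BD g cm-3, SOC g kg-1 per layer
CONTROL_SOIL_BD = (1.22, 1.22, 1.22)
CONTROL_SOIL_SOC = (2.60, 1.90, 2.00)

LAYER_ORDER = tuple(SOIL_LAYERS)  # ("0-10", "10-20", "20-50")

SITE_CYCLE = ("GULLY_BOTTOM", "SHADY_SLOPE", "SUNNY_SLOPE")

#: site-type multipliers on woody biomass / herb pools (gully > shady > sunny)
SITE_BIOMASS_FACTOR = {"GULLY_BOTTOM": 1.12, "SHADY_SLOPE": 1.00,
                       "SUNNY_SLOPE": 0.88}
SITE_HERB_FACTOR = {"GULLY_BOTTOM": 1.05, "SHADY_SLOPE": 1.00,
                    "SUNNY_SLOPE": 0.95}


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; defaults are the emulated study conditions."""

    n_rows: int = 36
    n_cols: int = 36
    cell_size: float = 30.0
    origin_x: float = 500000.0
    origin_y: float = 4420000.0
    crs_id: str = "EPSG:32649"
    years: tuple = tuple(range(2013, 2024))

    # climate
    temp_mean: float = 8.0            # degC annual mean
    temp_amplitude: float = 14.0      # degC seasonal half-range (peak July)
    temp_gradient: float = -1.0       # degC west->east across the grid
    temp_noise: float = 0.8           # degC additive s.d.
    precip_annual_mm: float = 320.0
    precip_gradient: float = 0.15     # fractional west->east increase
    precip_noise: float = 0.25        # lognormal sigma on monthly totals
    solar_mean: float = 450.0         # MJ m-2 month-1 annual mean
    solar_amplitude: float = 250.0    # seasonal half-range
    solar_noise: float = 10.0         # additive s.d.
    rnet_fraction: float = 0.55       # net radiation as share of solar

    # NDVI
    ndvi_base: float = 0.16           # winter-bare baseline amplitude source
    ndvi_gradient_x: float = 0.18     # west->east increase of summer NDVI
    ndvi_gradient_y: float = -0.06    # north->south change
    ndvi_age_increment: float = 0.012  # per-year greening of the maximum
    ndvi_noise: float = 0.02

    # DEM
    elev_base: float = 930.0          # m
    relief: float = 60.0              # m ridge-valley amplitude
    ridge_period_rows: int = 40       # rows per full ridge-valley cycle
    tilt_east: float = 0.01           # m per m gentle eastward dip

    # plot design (plots per stand age)
    plots_per_age: tuple = ((10, 7), (9, 4), (8, 6), (7, 7), (6, 6), (5, 6))
    quadrats_per_plot: int = 2
    subplots_per_quadrat: int = 2
    soil_points_per_plot: int = 3
    control_subplots_per_plot: int = 2
    control_soil_points_per_plot: int = 1
    quadrat_area_m2: float = 25.0
    subplot_area_m2: float = 1.0
    plants_per_quadrat: int = 20      # ~8000 stems ha-1

    # allometric truth (POWER_DH coefficients a, b, c, d; W kg, D cm, H m)
    allometric_above: tuple = (0.228, 0.1, 2.488, 0.006)
    allometric_below: tuple = (0.018, 0.1, 3.981, 0.073)
    n_standard_plants: int = 28
    biomass_sample_sigma: float = 0.1  # lognormal sigma on sampled W

    # morphometric / pool noise scales
    plant_cv: float = 0.15            # lognormal sigma on D and H draws
    herb_dry_ratio: float = 0.45      # oven-dry / fresh mass
    litter_dry_ratio: float = 0.65
    noise_herb: float = 6.0           # gC m-2 additive s.d.
    noise_litter: float = 3.0
    noise_soil_bd: float = 0.08       # g cm-3
    noise_soil_soc: float = 0.5       # g kg-1

    leakage_tco2_ha: float = DEFAULT_LEAKAGE_TCO2_HA
    seed: int = 0

    @property
    def meta(self) -> GridMeta:
        return GridMeta(self.n_rows, self.n_cols, self.cell_size,
                        self.origin_x, self.origin_y, self.crs_id)

    @property
    def months(self) -> list[str]:
        return [f"{y:04d}-{m:02d}" for y in self.years for m in range(1, 13)]


def _streams(spec: SynthSpec):
    ss = np.random.SeedSequence(spec.seed)
    names = ("climate", "ndvi", "dem", "plots", "biomass")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------- climate

def seasonal_temperature(spec: SynthSpec, month: int) -> float:
    """Climatological mean temperature for calendar month 1..12 (degC)."""
    return spec.temp_mean - spec.temp_amplitude * np.cos(
        2.0 * np.pi * (month - 1) / 12.0)


def _east_ramp(spec: SynthSpec) -> np.ndarray:
    cols = np.arange(spec.n_cols, dtype=float)
    denom = max(spec.n_cols - 1, 1)
    return np.tile(cols / denom, (spec.n_rows, 1))


def generate_climate(spec: SynthSpec):
    """Monthly temperature, precipitation, solar and net radiation stacks.

    Sinusoidal seasonal cycles (July peak) with a west->east spatial
    gradient and seeded noise; precipitation and radiation never negative.
    Units: degC, mm month-1, MJ m-2 month-1.
    """
    rng = _streams(spec)["climate"]
    ramp = _east_ramp(spec)
    months = spec.months
    t_layers, p_layers, s_layers, r_layers = [], [], [], []
    for label in months:
        m = int(label.split("-")[1])
        t_clim = seasonal_temperature(spec, m) + spec.temp_gradient * ramp
        t = t_clim + rng.normal(0.0, spec.temp_noise, size=ramp.shape) \
            if spec.temp_noise > 0 else t_clim
        p_clim = (spec.precip_annual_mm * PRECIP_MONTHLY_FRACTION[m - 1]
                  * (1.0 + spec.precip_gradient * ramp))
        if spec.precip_noise > 0:
            p = p_clim * rng.lognormal(0.0, spec.precip_noise, size=ramp.shape)
        else:
            p = p_clim * np.ones_like(ramp)
        s_clim = spec.solar_mean - spec.solar_amplitude * np.cos(
            2.0 * np.pi * (m - 1) / 12.0)
        s = s_clim + rng.normal(0.0, spec.solar_noise, size=ramp.shape) \
            if spec.solar_noise > 0 else s_clim * np.ones_like(ramp)
        s = np.maximum(s, 0.0)
        t_layers.append(np.broadcast_to(t, ramp.shape).copy())
        p_layers.append(np.maximum(p, 0.0))
        s_layers.append(s)
        r_layers.append(s * spec.rnet_fraction)
    meta = spec.meta

    def stack(layers):
        return MonthlyRasterStack(np.ma.asarray(np.stack(layers)),
                                  list(months), meta)

    log.info("synthetic climate: %d months on %dx%d grid (seed %d)",
             len(months), spec.n_rows, spec.n_cols, spec.seed)
    return stack(t_layers), stack(p_layers), stack(s_layers), stack(r_layers)


# ------------------------------------------------------------------ NDVI

def ndvi_season_weight(spec: SynthSpec, month: int) -> float:
    """Growing-season weight in [0, 1] from the climatological temperature."""
    t = seasonal_temperature(spec, month)
    hi = spec.temp_mean + spec.temp_amplitude
    if hi <= 5.0:
        return 0.0
    return float(np.clip((t - 5.0) / (hi - 5.0), 0.0, 1.0))


def ndvi_truth(spec: SynthSpec, row: int, col: int, year: int, month: int) -> float:
    """Closed-form noise-free NDVI of one cell (the generator's formula)."""
    denom_c = max(spec.n_cols - 1, 1)
    denom_r = max(spec.n_rows - 1, 1)
    base = (spec.ndvi_base + spec.ndvi_gradient_x * col / denom_c
            + spec.ndvi_gradient_y * row / denom_r)
    age_term = spec.ndvi_age_increment * (year - spec.years[0])
    s = ndvi_season_weight(spec, month)
    return float(np.clip((base + age_term) * s, 0.0, 1.0))


def generate_ndvi(spec: SynthSpec) -> MonthlyRasterStack:
    """Monthly NDVI: spatial gradient x seasonal shape + per-year greening.

    NDVI(x, y, year, m) = clip((base(x, y) + inc*(year-year0)) * s(m) + eps)
    where s(m) is the growing-season weight and eps is seeded noise.  With
    a positive increment and zero noise the annual maximum strictly
    increases year over year.
    """
    rng = _streams(spec)["ndvi"]
    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    cols = np.arange(spec.n_cols, dtype=float)[None, :]
    base = (spec.ndvi_base
            + spec.ndvi_gradient_x * cols / max(spec.n_cols - 1, 1)
            + spec.ndvi_gradient_y * rows / max(spec.n_rows - 1, 1))
    layers = []
    for label in spec.months:
        y, m = (int(t) for t in label.split("-"))
        s = ndvi_season_weight(spec, m)
        field_ = (base + spec.ndvi_age_increment * (y - spec.years[0])) * s
        if spec.ndvi_noise > 0:
            field_ = field_ + rng.normal(0.0, spec.ndvi_noise, size=base.shape)
        layers.append(np.clip(field_, 0.0, 1.0))
    return MonthlyRasterStack(np.ma.asarray(np.stack(layers)),
                              list(spec.months), spec.meta)


# ------------------------------------------------------------------- DEM

def generate_dem(spec: SynthSpec) -> np.ma.MaskedArray:
    """Smooth ridge-valley elevation surface (m).

    A north-south cosine ridge system plus a gentle eastward dip: slopes on
    the cosine flanks face due north/south (shady/sunny windows) and the
    crests/troughs are near-flat (gully window).
    """
    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    cols = np.arange(spec.n_cols, dtype=float)[None, :]
    z = (spec.elev_base
         + spec.relief * np.cos(2.0 * np.pi * rows / spec.ridge_period_rows)
         + spec.tilt_east * cols * spec.cell_size)
    return np.ma.asarray(np.broadcast_to(z, (spec.n_rows, spec.n_cols)).copy())


# ----------------------------------------------------------- plot truth

def _age_site_truth(spec: SynthSpec, age: float, site: str,
                    fractions: CarbonFractions = CarbonFractions()) -> dict:
    """Noise-free generator means for one (age, site) stratum.

    Woody pools are anchored to the reported stand-age pattern (net above
    rising from ~169 gC m-2 at age 5 to ~693 at age 10), realised through
    the allometric truth by solving mean plant height from the target
    above-ground pool; the below pool then follows from the same (D, H)
    through the below-ground form (allometric consistency).
    """
    fac = SITE_BIOMASS_FACTOR[site]
    above_target = (168.91 + (692.55 - 168.91) / 5.0 * (age - 5.0)) * fac
    d_mean = 0.8 + 0.12 * age
    a, b, c, d4 = spec.allometric_above
    w_above = (above_target / (fractions.above * 1000.0)
               * spec.quadrat_area_m2 / spec.plants_per_quadrat)
    h_mean = ((w_above - d4) / (a * d_mean ** b)) ** (1.0 / c)
    ab, bb, cb, db = spec.allometric_below
    w_below = ab * d_mean ** bb * h_mean ** cb + db
    below = (w_below * spec.plants_per_quadrat / spec.quadrat_area_m2
             * fractions.below * 1000.0)

    hfac = SITE_HERB_FACTOR[site]
    if age <= 7.0:
        herb = 39.0 + (20.01 - 39.0) / 2.0 * (age - 5.0)
    else:
        herb = 20.01 + (57.56 - 20.01) / 3.0 * (age - 7.0)
    herb *= hfac
    litter = 23.63 + (14.0 - 23.63) / 5.0 * (age - 5.0)

    bd, soc = SOIL_TRUTH[int(age)]
    socd = sum(
        s * r * SOIL_LAYERS[lay] * 10.0
        for lay, r, s in zip(LAYER_ORDER, bd, soc)
    )
    return {
        "d_mean": d_mean, "h_mean": h_mean,
        "above": above_target, "below": below,
        "herb": herb, "litter": litter,
        "soil": socd, "soil_bd": bd, "soil_soc": soc,
    }


def control_truth(spec: SynthSpec,
                  fractions: CarbonFractions = CarbonFractions()) -> CarbonPoolLedger:
    """Noise-free grassland baseline ledger (woody pools zero)."""
    socd = sum(
        s * r * SOIL_LAYERS[lay] * 10.0
        for lay, r, s in zip(LAYER_ORDER, CONTROL_SOIL_BD, CONTROL_SOIL_SOC)
    )
    return CarbonPoolLedger(plot="control", age=np.nan, site_type="GRASSLAND",
                            above=0.0, below=0.0, herb=34.0, litter=8.0,
                            soil=socd)


# -------------------------------------------------------- survey tables

def generate_plot_survey(spec: SynthSpec,
                         fractions: CarbonFractions = CarbonFractions()):
    """Generate all survey tables plus the per-plot ground-truth ledger.

    Returns a dict of DataFrames: ``plots``, ``plants``, ``herb_litter``,
    ``soil``, ``control_herb_litter``, ``control_soil``,
    ``biomass_samples`` (standard-plant destructive samples) and
    ``truth`` (noise-free per-plot ledger incl. totals).
    """
    rng = _streams(spec)["plots"]
    brng = _streams(spec)["biomass"]

    plots, plants, herb_litter, soil = [], [], [], []
    c_herb_litter, c_soil, truths = [], [], []
    plot_idx = 0
    for age, n_plots in spec.plots_per_age:
        for j in range(n_plots):
            site = SITE_CYCLE[plot_idx % len(SITE_CYCLE)]
            pid = f"P{age:02d}-{j + 1:02d}"
            tr = _age_site_truth(spec, age, site, fractions)
            plots.append({"plot": pid, "age_yr": age, "site_type": site,
                          "quadrat_area_m2": spec.quadrat_area_m2})
            truths.append(CarbonPoolLedger(
                plot=pid, age=age, site_type=site,
                above=tr["above"], below=tr["below"], herb=tr["herb"],
                litter=tr["litter"], soil=tr["soil"]))

            for q in range(1, spec.quadrats_per_plot + 1):
                for _ in range(spec.plants_per_quadrat):
                    if spec.plant_cv > 0:
                        dmul = rng.lognormal(0.0, spec.plant_cv)
                        hmul = rng.lognormal(0.0, spec.plant_cv)
                    else:
                        dmul = hmul = 1.0
                    plants.append({
                        "plot": pid, "quadrat": q,
                        "D_cm": tr["d_mean"] * dmul,
                        "H_m": tr["h_mean"] * hmul,
                        "crown_m": 0.8 * tr["h_mean"] * hmul,
                    })
                for sp in range(1, spec.subplots_per_quadrat + 1):
                    sub_id = (q - 1) * spec.subplots_per_quadrat + sp
                    for comp, dens, frac, ratio, nz in (
                        ("herb", tr["herb"], fractions.herb,
                         spec.herb_dry_ratio, spec.noise_herb),
                        ("litter", tr["litter"], fractions.litter,
                         spec.litter_dry_ratio, spec.noise_litter),
                    ):
                        cdens = dens
                        if nz > 0:
                            cdens = max(cdens + rng.normal(0.0, nz), 0.0)
                        dry_kg = cdens / (frac * 1000.0) * spec.subplot_area_m2
                        herb_litter.append({
                            "plot": pid, "subplot": sub_id, "compartment": comp,
                            "fresh_kg": dry_kg / ratio,
                            "sub_fresh_g": 200.0,
                            "sub_dry_g": 200.0 * ratio,
                            "area_m2": spec.subplot_area_m2,
                        })
            for pt in range(1, spec.soil_points_per_plot + 1):
                for lay, bd_t, soc_t in zip(LAYER_ORDER, tr["soil_bd"],
                                            tr["soil_soc"]):
                    bd = bd_t
                    soc = soc_t
                    if spec.noise_soil_bd > 0:
                        bd = float(np.clip(
                            bd + rng.normal(0.0, spec.noise_soil_bd),
                            0.51, 2.19))
                    if spec.noise_soil_soc > 0:
                        soc = max(soc + rng.normal(0.0, spec.noise_soil_soc),
                                  0.0)
                    soil.append({"plot": pid, "point": pt, "layer": lay,
                                 "bd_g_cm3": bd, "soc_g_kg": soc})

            ctr = control_truth(spec, fractions)
            for sp in range(1, spec.control_subplots_per_plot + 1):
                for comp, dens, frac, ratio, nz in (
                    ("herb", ctr.herb, fractions.herb,
                     spec.herb_dry_ratio, spec.noise_herb),
                    ("litter", ctr.litter, fractions.litter,
                     spec.litter_dry_ratio, spec.noise_litter),
                ):
                    cdens = dens
                    if nz > 0:
                        cdens = max(cdens + rng.normal(0.0, nz), 0.0)
                    dry_kg = cdens / (frac * 1000.0) * spec.subplot_area_m2
                    c_herb_litter.append({
                        "plot": pid, "subplot": sp, "compartment": comp,
                        "fresh_kg": dry_kg / ratio,
                        "sub_fresh_g": 200.0,
                        "sub_dry_g": 200.0 * ratio,
                        "area_m2": spec.subplot_area_m2,
                    })
            for pt in range(1, spec.control_soil_points_per_plot + 1):
                for lay, bd_t, soc_t in zip(LAYER_ORDER, CONTROL_SOIL_BD,
                                            CONTROL_SOIL_SOC):
                    bd, soc = bd_t, soc_t
                    if spec.noise_soil_bd > 0:
                        bd = float(np.clip(
                            bd + rng.normal(0.0, spec.noise_soil_bd),
                            0.51, 2.19))
                    if spec.noise_soil_soc > 0:
                        soc = max(soc + rng.normal(0.0, spec.noise_soil_soc),
                                  0.0)
                    c_soil.append({"plot": pid, "point": pt, "layer": lay,
                                   "bd_g_cm3": bd, "soc_g_kg": soc})
            plot_idx += 1

    # destructive standard-plant samples spanning the age range
    samples = []
    ages = [a for a, _ in spec.plots_per_age]
    for i in range(spec.n_standard_plants):
        age = ages[i % len(ages)]
        tr = _age_site_truth(spec, age, SITE_CYCLE[i % 3], fractions)
        dmul = brng.lognormal(0.0, spec.plant_cv) if spec.plant_cv > 0 else 1.0
        hmul = brng.lognormal(0.0, spec.plant_cv) if spec.plant_cv > 0 else 1.0
        d_i, h_i = tr["d_mean"] * dmul, tr["h_mean"] * hmul
        a, b, c, d4 = spec.allometric_above
        ab, bb, cb, db = spec.allometric_below
        wt = a * d_i ** b * h_i ** c + d4
        wd = ab * d_i ** bb * h_i ** cb + db
        if spec.biomass_sample_sigma > 0:
            wt *= brng.lognormal(0.0, spec.biomass_sample_sigma)
            wd *= brng.lognormal(0.0, spec.biomass_sample_sigma)
        samples.append({"plant": i + 1, "age_yr": age, "D_cm": d_i,
                        "H_m": h_i, "Wt_kg": wt, "Wd_kg": wd})

    truth_df = pd.DataFrame([t.as_dict() for t in truths])
    log.info("synthetic survey: %d plots, %d plant rows, %d herb/litter rows,"
             " %d soil rows", len(plots), len(plants), len(herb_litter),
             len(soil))
    return {
        "plots": pd.DataFrame(plots),
        "plants": pd.DataFrame(plants),
        "herb_litter": pd.DataFrame(herb_litter),
        "soil": pd.DataFrame(soil),
        "control_herb_litter": pd.DataFrame(c_herb_litter),
        "control_soil": pd.DataFrame(c_soil),
        "biomass_samples": pd.DataFrame(samples),
        "truth": truth_df,
    }


def assign_plot_cells(plots: pd.DataFrame, site_grid, seed: int = 0) -> pd.DataFrame:
    """Attach a (row, col) grid cell of the matching site type to each plot."""
    from .terrain import SiteType

    rng = np.random.default_rng(seed)
    zones = np.ma.filled(np.ma.asarray(site_grid), -1)
    out = plots.copy()
    rows, cols = [], []
    for _, r in plots.iterrows():
        code = SiteType[r["site_type"]].value
        cand = np.argwhere(zones == code)
        if cand.size == 0:
            cand = np.argwhere(zones >= 0)
        pick = cand[rng.integers(0, len(cand))]
        rows.append(int(pick[0]))
        cols.append(int(pick[1]))
    out["row"], out["col"] = rows, cols
    return out
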