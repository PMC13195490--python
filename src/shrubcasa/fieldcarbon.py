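"""Plot-level carbon accounting for shrub plantation surveys.

Pipeline: allometric biomass models (fit on destructively sampled standard
plants, applied to every measured individual), herbaceous/litter carbon
from fresh weights and oven-dry subsample ratios, layered soil organic
carbon density, aggregation into a per-plot five-pool ledger (above,
below, herb, litter, soil; gC m-2), and net sequestration after
subtracting a native-grassland baseline and afforestation machinery
emissions (carbon leakage).

Two allometric forms are supported:

    CUBIC_H : W = c1*H + c2*H^2 + c3*H^3 + c0          (linear in coef.)
    POWER_DH: W = a * D^b * H^c + d                    (nonlinear)

with W in kg, ground diameter D in cm, height H in m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .nep import gc_m2_to_tco2_ha

log = logging.getLogger(__name__)

#: depth intervals sampled (cm) and their thicknesses
SOIL_LAYERS = {"0-10": 10.0, "10-20": 10.0, "20-50": 30.0}

DEFAULT_LEAKAGE_TCO2_HA = 3.31
DEFAULT_QUADRAT_AREA_M2 = 25.0


@dataclass(frozen=True)
class CarbonFractions:
    """Mass fraction of carbon in dry biomass per pool.

    Above-ground uses the mean of leaf/branch-stem contents for this
    species; below-ground is the root content; herb and litter follow CDM
    defaults.
    """

    above: float = 0.5465
    below: float = 0.4526
    herb: float = 0.40
    litter: float = 0.37

    def __post_init__(self) -> None:
        for name in ("above", "below", "herb", "litter"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"carbon fraction {name} must lie in (0,1)")


class ModelForm(Enum):
    CUBIC_H = "cubic_h"
    POWER_DH = "power_dh"


class Component(Enum):
    ABOVE = "above"
    BELOW = "below"


@dataclass
class AllometricModel:
    """Biomass ~ morphometrics regression with an sklearn-like surface.

    After :meth:`fit`, ``coef_`` holds (c0, c1, c2, c3) for CUBIC_H or
    (a, b, c, d) for POWER_DH, and ``r_squared_`` the in-sample R^2.
    """

    form: ModelForm = ModelForm.POWER_DH
    component: Component = Component.ABOVE
    n_restarts: int = 4
    seed: int = 0

    coef_: tuple = field(default=None, init=False, repr=False)
    r_squared_: float = field(default=None, init=False, repr=False)
    n_samples_: int = field(default=None, init=False, repr=False)

    def fit(self, d, h, w, exclude=None) -> "AllometricModel":
        """Fit on standard-plant samples (D cm, H m, biomass W kg).

        ``exclude`` is an optional boolean mask of samples the analyst has
        flagged as outliers; excluded rows do not enter the fit.
        """
        d = np.asarray(d, dtype=float)
        h = np.asarray(h, dtype=float)
        w = np.asarray(w, dtype=float)
        if exclude is not None:
            keep = ~np.asarray(exclude, dtype=bool)
            d, h, w = d[keep], h[keep], w[keep]
        if d.size < 6:
            raise ValueError(f"need at least 6 samples, got {d.size}")
        if np.any(d <= 0) or np.any(h <= 0) or np.any(w <= 0):
            raise ValueError("D, H and biomass must all be positive")
        sst = float(np.sum((w - w.mean()) ** 2))
        if sst == 0:
            raise ValueError("constant biomass samples: R^2 undefined (SST = 0)")

        if self.form is ModelForm.CUBIC_H:
            X = np.column_stack([np.ones_like(h), h, h * h, h ** 3])
            coef, *_ = np.linalg.lstsq(X, w, rcond=None)
            pred = X @ coef
            self.coef_ = tuple(float(x) for x in coef)
        else:
            self.coef_, pred = self._fit_power(d, h, w)
        sse = float(np.sum((w - pred) ** 2))
        self.r_squared_ = 1.0 - sse / sst
        self.n_samples_ = int(d.size)
        log.info("fitted %s %s model on %d plants: coef=%s R2=%.4f",
                 self.form.value, self.component.value, self.n_samples_,
                 np.round(self.coef_, 4), self.r_squared_)
        return self

    def _fit_power(self, d, h, w):
        def resid(theta):
            a, b, c, dd = theta
            return a * d ** b * h ** c + dd - w

        # log-linearised start: take d0 = min(W)/2, regress log(W - d0)
        d0 = float(w.min()) / 2.0
        y = np.log(w - d0)
        X = np.column_stack([np.ones_like(y), np.log(d), np.log(h)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        starts = [np.array([np.exp(beta[0]), beta[1], beta[2], d0])]
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_restarts):
            jit = starts[0] * rng.uniform(0.5, 1.5, size=4)
            jit[3] = starts[0][3] * rng.uniform(0.0, 1.0)
            starts.append(jit)

        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, method="lm",
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                    max_nfev=20000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("power-law biomass fit failed from every start")
        grad_norm = float(np.linalg.norm(best.jac.T @ best.fun))
        if not best.success and grad_norm > 1e-10:
            raise RuntimeError(
                f"power-law biomass fit did not converge "
                f"(best residual SS {2 * best.cost:.6g}, grad {grad_norm:.2e})"
            )
        coef = tuple(float(x) for x in best.x)
        return coef, resid(best.x) + w

    def predict(self, d, h) -> np.ndarray:
        """Per-plant biomass (kg) from D (cm) and H (m)."""
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        d = np.asarray(d, dtype=float)
        h = np.asarray(h, dtype=float)
        if self.form is ModelForm.CUBIC_H:
            c0, c1, c2, c3 = self.coef_
            return c0 + c1 * h + c2 * h * h + c3 * h ** 3
        a, b, c, dd = self.coef_
        return a * d ** b * h ** c + dd

    @classmethod
    def from_coefficients(cls, form: ModelForm, coef,
                          component: Component = Component.ABOVE):
        m = cls(form=form, component=component)
        m.coef_ = tuple(float(x) for x in coef)
        return m


def fit_allometric(samples, form: ModelForm, component: Component = Component.ABOVE,
                   exclude=None, seed: int = 0) -> AllometricModel:
    """Functional wrapper: ``samples`` is an iterable of (D, H, W) triples."""
    arr = np.asarray(list(samples), dtype=float)
    model = AllometricModel(form=form, component=component, seed=seed)
    return model.fit(arr[:, 0], arr[:, 1], arr[:, 2], exclude=exclude)


def predict_biomass(model: AllometricModel, plants,
                    quadrat_area: float = DEFAULT_QUADRAT_AREA_M2) -> float:
    """Quadrat biomass density (kg m-2): per-plant predictions summed / area.

    ``plants`` is an iterable of (D, H) pairs for one quadrat.  Negative
    per-plant predictions are clipped to zero with a warning.
    """
    if quadrat_area <= 0:
        raise ValueError("quadrat_area must be positive")
    plants = list(plants)
    if not plants:
        return 0.0
    arr = np.asarray(plants, dtype=float)
    pred = model.predict(arr[:, 0], arr[:, 1])
    if np.any(pred < 0):
        warnings.warn(
            f"{int((pred < 0).sum())} negative per-plant biomass predictions "
            "clipped to 0", RuntimeWarning, stacklevel=2)
        pred = np.clip(pred, 0.0, None)
    return float(pred.sum() / quadrat_area)


def herb_litter_carbon(fresh_total_kg: float, subsample_fresh_g: float,
                       subsample_dry_g: float, subplot_area_m2: float,
                       fraction: float) -> float:
    """Subplot carbon density (gC m-2) from fresh weight and dry ratio.

    dry density = fresh_total * (dry/fresh) / area (kg m-2);
    carbon = dry density * fraction * 1000 (kg -> g).
    """
    if subplot_area_m2 <= 0 or subsample_fresh_g <= 0:
        raise ValueError("areas and subsample fresh weight must be positive")
    if subsample_dry_g > subsample_fresh_g:
        raise ValueError("subsample dry weight exceeds fresh weight")
    ratio = subsample_dry_g / subsample_fresh_g
    dry_density = fresh_total_kg * ratio / subplot_area_m2
    return dry_density * fraction * 1000.0


def soil_carbon_density(layers):
    """Soil organic carbon density SOCD = sum_i SOC_i * rho_i * H_i * 10.

    ``layers`` is an iterable of (layer_label, bulk_density g cm-3,
    SOC g kg-1) with labels from :data:`SOIL_LAYERS`.  Returns
    (total gC m-2, {layer: gC m-2}).
    """
    per_layer: dict[str, float] = {}
    for label, bd, soc in layers:
        if label not in SOIL_LAYERS:
            raise ValueError(f"unknown soil layer {label!r}; "
                             f"expected one of {sorted(SOIL_LAYERS)}")
        if label in per_layer:
            raise ValueError(f"duplicate soil layer {label!r}")
        if soc < 0:
            raise ValueError("SOC must be non-negative")
        per_layer[label] = soc * bd * SOIL_LAYERS[label] * 10.0
    return float(sum(per_layer.values())), per_layer


@dataclass
class CarbonPoolLedger:
    """Per-plot carbon density by pool (gC m-2); total is the exact sum."""

    plot: str
    age: float
    site_type: str
    above: float
    below: float
    herb: float
    litter: float
    soil: float

    @property
    def total(self) -> float:
        return self.above + self.below + self.herb + self.litter + self.soil

    def as_dict(self) -> dict:
        return {"plot": self.plot, "age_yr": self.age,
                "site_type": self.site_type, "above": self.above,
                "below": self.below, "herb": self.herb, "litter": self.litter,
                "soil": self.soil, "total": self.total}


@dataclass
class NetSequestration:
    """Gross/baseline/leakage/net, all tCO2 ha-1; net = gross - baseline - leakage."""

    gross: float
    baseline: float
    leakage: float

    @property
    def net(self) -> float:
        return self.gross - self.baseline - self.leakage


def build_ledger(plot_row: pd.Series | dict,
                 plants: pd.DataFrame,
                 herb_litter: pd.DataFrame,
                 soil: pd.DataFrame,
                 above_model: AllometricModel,
                 below_model: AllometricModel,
                 fractions: CarbonFractions = CarbonFractions()) -> CarbonPoolLedger:
    """Assemble one plot's five-pool ledger from its survey tables.

    ``plants`` needs columns quadrat, D_cm, H_m; ``herb_litter`` columns
    subplot, compartment ("herb"/"litter"), fresh_kg, sub_fresh_g,
    sub_dry_g, area_m2; ``soil`` columns point, layer, bd_g_cm3, soc_g_kg.
    Woody pools average over quadrats, herb/litter over subplots, soil over
    sampling points.
    """
    row = dict(plot_row)
    area = float(row.get("quadrat_area_m2", DEFAULT_QUADRAT_AREA_M2))

    def _pool_biomass(model):
        densities = []
        for _, q in plants.groupby("quadrat"):
            densities.append(
                predict_biomass(model, zip(q["D_cm"], q["H_m"]), area))
        return float(np.mean(densities)) if densities else 0.0

    missing = []
    if plants.empty and not row.get("control", False):
        missing.append("plants")
    for comp in ("herb", "litter"):
        if herb_litter[herb_litter["compartment"] == comp].empty:
            missing.append(comp)
    if soil.empty:
        missing.append("soil")
    if missing:
        raise ValueError(
            f"plot {row.get('plot')}: missing compartment(s) {', '.join(missing)}")

    above_density = _pool_biomass(above_model)
    below_density = _pool_biomass(below_model)

    def _hl(comp, frac):
        sub = herb_litter[herb_litter["compartment"] == comp]
        vals = [herb_litter_carbon(r.fresh_kg, r.sub_fresh_g, r.sub_dry_g,
                                   r.area_m2, frac)
                for r in sub.itertuples()]
        return float(np.mean(vals))

    socds = []
    for _, pt in soil.groupby("point"):
        total, _ = soil_carbon_density(
            zip(pt["layer"], pt["bd_g_cm3"], pt["soc_g_kg"]))
        socds.append(total)

    return CarbonPoolLedger(
        plot=str(row.get("plot")),
        age=float(row.get("age_yr", np.nan)),
        site_type=str(row.get("site_type", "")),
        above=above_density * fractions.above * 1000.0,
        below=below_density * fractions.below * 1000.0,
        herb=_hl("herb", fractions.herb),
        litter=_hl("litter", fractions.litter),
        soil=float(np.mean(socds)),
    )


def net_sequestration(project: CarbonPoolLedger, control: CarbonPoolLedger,
                      leakage: float = DEFAULT_LEAKAGE_TCO2_HA,
                      poolwise: bool = True) -> NetSequestration:
    """Net density = gross - grassland baseline - machinery leakage (tCO2 ha-1).

    The control ledger carries the grassland's herb/litter/soil pools
    (woody pools zero).  ``poolwise`` subtracts pool-by-pool before
    totalling (the default); the total-wise alternative gives the same net
    by linearity but is offered for reporting symmetry.
    """
    gross = gc_m2_to_tco2_ha(project.total)
    if poolwise:
        base = sum(
            gc_m2_to_tco2_ha(getattr(control, p))
            for p in ("above", "below", "herb", "litter", "soil")
        )
    else:
        base = gc_m2_to_tco2_ha(control.total)
    return NetSequestration(gross=float(gross), baseline=float(base),
                            leakage=float(leakage))


def ledgers_to_frame(ledgers) -> pd.DataFrame:
    return pd.DataFrame([l.as_dict() for l in ledgers])
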