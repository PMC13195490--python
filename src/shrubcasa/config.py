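"""Flat key-value run configuration.

The config format is one ``key = value`` assignment per line (``#``
comments and blank lines ignored) — deliberately dialect-free.  Unknown
keys are rejected; CASA and respiration parameter overrides are validated
against their documented legal ranges at load time and every stage logs
the values actually used.

Recognised keys::

    ndvi, tmean, precip, solar, rnet   path patterns with {month}
    dem                                DEM GeoTIFF path
    plots, plants, herb_litter, soil, control_herb_litter, control_soil,
    biomass_samples                    plot-survey CSV paths
    start, end                         month range, YYYY-MM inclusive
    outdir                             output directory
    seed                               integer random seed
    ndvi_max ndvi_min fpar_max fpar_min epsilon_max t_opt par_fraction
    resp_b resp_f resp_k rh_intercept rh_slope
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as _dcfields

from .casa import CasaParams
from .nep import RespirationParams
from .raster import month_range

log = logging.getLogger(__name__)

_PATH_KEYS = (
    "ndvi", "tmean", "precip", "solar", "rnet", "dem",
    "plots", "plants", "herb_litter", "soil",
    "control_herb_litter", "control_soil", "biomass_samples",
)
_CASA_KEYS = {
    "ndvi_max", "ndvi_min", "fpar_max", "fpar_min",
    "epsilon_max", "t_opt", "par_fraction",
}
_RESP_KEYS = {"resp_b": "b", "resp_f": "f", "resp_k": "k",
              "rh_intercept": "rh_intercept", "rh_slope": "rh_slope"}

#: documented legal ranges for overridable parameters (open/closed noted
#: in the message text)
_BOUNDS = {
    "ndvi_max": (0.0, 1.0, "ndvi_max must lie in (0,1]"),
    "ndvi_min": (-1.0, 1.0, "ndvi_min must lie in [-1,1)"),
    "fpar_max": (0.0, 1.0, "fpar_max must lie in (0,1]"),
    "fpar_min": (0.0, 1.0, "fpar_min must lie in [0,1)"),
    "epsilon_max": (0.0, 10.0, "epsilon_max must lie in (0,10]"),
    "t_opt": (-10.0, 45.0, "t_opt must lie in [-10,45]"),
    "par_fraction": (0.0, 1.0, "par_fraction must lie in (0,1)"),
    "resp_b": (-1.0, 1.0, "resp_b must lie in [-1,1]"),
    "resp_f": (0.0, 100.0, "resp_f must lie in (0,100]"),
    "resp_k": (0.0, 100.0, "resp_k must lie in (0,100]"),
    "rh_intercept": (-10.0, 10.0, "rh_intercept must lie in [-10,10]"),
    "rh_slope": (0.0, 10.0, "rh_slope must lie in (0,10]"),
}


@dataclass
class RunConfig:
    """Validated run configuration with all defaults applied."""

    paths: dict = field(default_factory=dict)
    casa: CasaParams = field(default_factory=CasaParams)
    respiration: RespirationParams = field(default_factory=RespirationParams)
    start: str = "2013-01"
    end: str = "2023-12"
    outdir: str = "out"
    seed: int = 0

    @property
    def months(self) -> list[str]:
        return month_range(self.start, self.end)


def _check_bound(key: str, value: float) -> float:
    lo, hi, msg = _BOUNDS[key]
    text = msg.split("lie in ")[1]
    lo_open = text.startswith("(")
    hi_open = text.endswith(")")
    ok = (value > lo if lo_open else value >= lo) and \
         (value < hi if hi_open else value <= hi)
    if not ok:
        raise ValueError(msg)
    return value


def parse_config_text(text: str) -> RunConfig:
    paths: dict = {}
    casa_over: dict = {}
    resp_over: dict = {}
    extra: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _PATH_KEYS:
            paths[key] = value
        elif key in _CASA_KEYS:
            casa_over[key] = _check_bound(key, float(value))
        elif key in _RESP_KEYS:
            resp_over[_RESP_KEYS[key]] = _check_bound(key, float(value))
        elif key in ("start", "end", "outdir"):
            extra[key] = value
        elif key == "seed":
            extra[key] = int(value)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
    cfg = RunConfig(paths=paths,
                    casa=CasaParams(**casa_over),
                    respiration=RespirationParams(**resp_over),
                    **extra)
    cfg.months  # validates the range is non-empty and well-formed
    log.info("config: months %s..%s, seed %d, %d paths, CASA overrides %s",
             cfg.start, cfg.end, cfg.seed, len(paths),
             sorted(casa_over) or "none")
    return cfg


def load_config(path: str) -> RunConfig:
    """Load and validate a flat key-value config file."""
    with open(path, encoding="utf-8") as fh:
        return parse_config_text(fh.read())
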