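"""Seeded synthetic soil surveys, pH grids and deposition histories.

The generator emulates the qualitative micro-spatial structure that the
analysis modules are designed to detect, without claiming any real
site's values:

* an early (1983-type) survey whose topsoil pH rises monotonically with
  downhill distance from the stem, with a configurable amplitude
  (default 3.0 pH units) that attenuates with depth;
* a late (2010-type) survey whose topsoil gradient has flattened and
  crossed over (higher than 1983 near the stem, lower at 3 m), while
  deep horizons below a distance-dependent acidification front are
  *lower* than in 1983 (front migration, deeper near the stem);
* exchangeable Ca and Mg stores increasing downhill, the depletion
  concentrated in the deep soil near the stem;
* total-S profile stores that are distance-flat at a configurable target
  within 0.7-1.0 t ha-1;
* radially symmetric pH grids around the stem matching the topsoil
  profile;
* noisy realizations of the deterministic deposition trajectories.

Noise is independent Gaussian per cell (no spatial autocorrelation);
identical seeds yield identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gradients import (
    CANONICAL_DISTANCES_CM,
    CANONICAL_HORIZONS,
    HorizonSpec,
    SurveyPair,
)
from .recovery import (
    DepositionScenario,
    build_input_trajectory,
    build_output_trajectory,
)

log = logging.getLogger(__name__)

PH_MIN, PH_MAX = 2.0, 9.0
BD_MIN, BD_MAX = 0.1, 2.5

#: Noise-capable survey variables (column names in the emitted table).
NOISE_VARIABLES = (
    "ph_h2o",
    "ca_exch_mg_g",
    "mg_exch_mg_g",
    "c_mg_g",
    "n_mg_g",
    "s_mg_g",
    "bulk_density_g_cm3",
)


def _default_recovered_counts() -> dict[float, int]:
    # horizons recovered (delta-pH >= 0) per distance in the late survey;
    # more near the stem, none from 150 cm outwards and uphill
    return {-55.0: 0, 27.0: 3, 55.0: 2, 100.0: 1, 150.0: 0, 300.0: 0}


@dataclass
class SyntheticSurveyConfig:
    """Parameters of the synthetic paired soil survey.

    pH anchors and store targets are noiseless expectations; per-variable
    Gaussian noise is opt-in via ``noise_sd`` (column name -> sd).  The
    1983 topsoil amplitude ``ph_far_1983 - ph_stem_1983`` may not exceed
    3 pH units.  Values not constrained by published ranges (Ca/Mg store
    levels, 2010 anchors, noise) are invented fixtures.
    """

    seed: int = 0
    sites: tuple[str, ...] = ("SyntheticSite",)
    distances_cm: tuple[float, ...] = CANONICAL_DISTANCES_CM
    horizons: tuple[HorizonSpec, ...] = CANONICAL_HORIZONS
    early_year: int = 1983
    late_year: int = 2010
    ph_stem_1983: float = 3.5
    ph_far_1983: float = 6.5
    ph_stem_2010_top: float = 5.5
    ph_far_2010_top: float = 5.0
    deep_acidification_shift: float = -0.4
    recovered_gain: float = 0.2
    ca_far_store: float = 6.0
    mg_far_store: float = 0.8
    ca_stem_depletion: float = 0.6
    s_profile_target: float = 0.85
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    replicates: int = 1
    profile_shape: str = "log"
    recovered_horizon_counts: Mapping[float, int] = field(
        default_factory=_default_recovered_counts
    )
    # per-horizon fixtures (aligned with ``horizons``)
    bulk_density: tuple[float, ...] = (0.8, 1.0, 1.2, 1.3, 1.4)
    depth_attenuation: tuple[float, ...] = (1.0, 0.85, 0.70, 0.55, 0.40)
    depletion_weight: tuple[float, ...] = (0.5, 0.6, 0.8, 1.0, 1.0)
    c_conc_mg_g: tuple[float, ...] = (55.0, 35.0, 18.0, 9.0, 5.0)
    cn_ratio: float = 12.0

    def __post_init__(self) -> None:
        if self.ph_far_1983 - self.ph_stem_1983 > 3.0 + 1e-12:
            raise ConfigError(
                "ph_far_1983 - ph_stem_1983 exceeds the 3-unit amplitude bound"
            )
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.profile_shape not in ("log", "linear"):
            raise ConfigError("profile_shape must be 'log' or 'linear'")
        if self.early_year >= self.late_year:
            raise ConfigError("early_year must precede late_year")
        if not 0 <= self.ca_stem_depletion < 1:
            raise ConfigError("ca_stem_depletion must lie in [0, 1)")
        if not 0.7 <= self.s_profile_target <= 1.0:
            raise ConfigError("s_profile_target must lie in [0.7, 1.0] t/ha")
        for k, v in self.noise_sd.items():
            if k not in NOISE_VARIABLES:
                raise ConfigError(f"noise_sd: unknown variable {k!r}")
            if v < 0:
                raise ConfigError(f"noise_sd[{k!r}] must be >= 0")
        n = len(self.horizons)
        for name in ("bulk_density", "depth_attenuation", "depletion_weight", "c_conc_mg_g"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"{name} must have one entry per horizon")
        missing = [d for d in self.distances_cm if d not in self.recovered_horizon_counts]
        if missing:
            raise ConfigError(f"recovered_horizon_counts missing distances {missing}")
        if not any(d > 0 for d in self.distances_cm):
            raise ConfigError("at least one downhill distance is required")

    # -- noiseless expectations -------------------------------------------

    def gradient_position(self, distance_cm: float) -> float:
        """Relative position g in [0, 1] along the downhill gradient.

        0 at the nearest sampled downhill distance, 1 at the farthest;
        uphill columns sit outside the stemflow track and take g = 1.
        Default shape is logarithmic in distance (steep change near the
        stem, as stemflow infiltration maps suggest).
        """
        down = sorted(d for d in self.distances_cm if d > 0)
        dmin, dmax = down[0], down[-1]
        if distance_cm <= 0:
            return 1.0
        d = min(max(distance_cm, dmin), dmax)
        if self.profile_shape == "log":
            return math.log(d / dmin) / math.log(dmax / dmin)
        return (d - dmin) / (dmax - dmin)

    def expected_ph(self, distance_cm: float, horizon_index: int, year: int) -> float:
        """Noiseless pH of one cell."""
        g = self.gradient_position(distance_cm)
        amp = self.ph_far_1983 - self.ph_stem_1983
        p83 = self.ph_far_1983 - amp * self.depth_attenuation[horizon_index] * (1 - g)
        if year == self.early_year:
            return p83
        if horizon_index == 0:
            return self.ph_stem_2010_top + (
                self.ph_far_2010_top - self.ph_stem_2010_top
            ) * g
        n_rec = self.recovered_horizon_counts[distance_cm]
        if horizon_index < n_rec:
            return p83 + self.recovered_gain
        return p83 + self.deep_acidification_shift

    def _bd_thickness_sum(self) -> float:
        return sum(
            bd * h.thickness_cm for bd, h in zip(self.bulk_density, self.horizons)
        )

    def expected_concentration(
        self, element: str, distance_cm: float, horizon_index: int
    ) -> float:
        """Noiseless mg g-1 concentration of one cell (same both years)."""
        g = self.gradient_position(distance_cm)
        denom = 0.1 * self._bd_thickness_sum()
        if element == "s":
            return self.s_profile_target / denom
        if element in ("ca", "mg"):
            far = (self.ca_far_store if element == "ca" else self.mg_far_store) / denom
            depletion = (
                self.ca_stem_depletion
                * self.depletion_weight[horizon_index]
                * (1 - g)
            )
            return far * (1 - depletion)
        if element == "c":
            return self.c_conc_mg_g[horizon_index]
        if element == "n":
            return self.c_conc_mg_g[horizon_index] / self.cn_ratio
        raise ConfigError(f"unknown element {element!r}")


def _clip_logged(values: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    clipped = np.clip(values, lo, hi)
    n = int(np.sum(clipped != values))
    if n:
        log.warning("clipped %d %s values into [%g, %g]", n, name, lo, hi)
    return clipped


def _one_survey(
    config: SyntheticSurveyConfig, year: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for site in config.sites:
        for dist in config.distances_cm:
            for h_idx, horizon in enumerate(config.horizons):
                for rep in range(1, config.replicates + 1):
                    rows.append(
                        {
                            "site": site,
                            "survey_year": year,
                            "distance_cm": dist,
                            "horizon_top_cm": horizon.top_cm,
                            "horizon_bottom_cm": horizon.bottom_cm,
                            "replicate": rep,
                            "ph_h2o": config.expected_ph(dist, h_idx, year),
                            "ca_exch_mg_g": config.expected_concentration("ca", dist, h_idx),
                            "mg_exch_mg_g": config.expected_concentration("mg", dist, h_idx),
                            "c_mg_g": config.expected_concentration("c", dist, h_idx),
                            "n_mg_g": config.expected_concentration("n", dist, h_idx),
                            "s_mg_g": config.expected_concentration("s", dist, h_idx),
                            "bulk_density_g_cm3": config.bulk_density[h_idx],
                        }
                    )
    df = pd.DataFrame(rows)
    for col in NOISE_VARIABLES:
        sd = config.noise_sd.get(col, 0.0)
        if sd > 0:
            df[col] = df[col] + rng.normal(0.0, sd, size=len(df))
    df["ph_h2o"] = _clip_logged(df["ph_h2o"].to_numpy(), PH_MIN + 1e-6, PH_MAX - 1e-6, "pH")
    df["bulk_density_g_cm3"] = _clip_logged(
        df["bulk_density_g_cm3"].to_numpy(), BD_MIN + 1e-6, BD_MAX - 1e-6, "bulk density"
    )
    for col in ("ca_exch_mg_g", "mg_exch_mg_g", "c_mg_g", "n_mg_g", "s_mg_g"):
        df[col] = _clip_logged(df[col].to_numpy(), 0.0, np.inf, col)
    return df


def generate_survey(config: SyntheticSurveyConfig) -> SurveyPair:
    """Generate the aligned early/late survey pair."""
    rng = np.random.default_rng(config.seed)
    early = _one_survey(config, config.early_year, rng)
    late = _one_survey(config, config.late_year, rng)
    return SurveyPair(early=early, late=late)


def generate_grid(
    config: SyntheticSurveyConfig,
    extent_cm: float = 300.0,
    spacing_cm: float = 50.0,
    year: int | None = None,
) -> pd.DataFrame:
    """Radially symmetric topsoil pH grid around the stem at (0, 0).

    The noiseless expectation at radius r equals the survey's topsoil pH
    at downhill distance r (clamped to the sampled range), for the
    requested survey year (default: the early year).
    """
    if spacing_cm <= 0:
        raise ConfigError("spacing_cm must be > 0")
    if extent_cm < spacing_cm:
        raise ConfigError("extent_cm must be >= spacing_cm")
    year = config.early_year if year is None else year
    if year not in (config.early_year, config.late_year):
        raise ConfigError(f"year must be {config.early_year} or {config.late_year}")
    rng = np.random.default_rng(config.seed + 1)
    axis = np.arange(-extent_cm, extent_cm + spacing_cm / 2, spacing_cm)
    xx, yy = np.meshgrid(axis, axis)
    x, y = xx.ravel(), yy.ravel()
    r = np.hypot(x, y)
    dmin = min(d for d in config.distances_cm if d > 0)
    ph = np.array(
        [config.expected_ph(max(ri, dmin), 0, year) for ri in r]
    )
    sd = config.noise_sd.get("ph_h2o", 0.0)
    if sd > 0:
        ph = ph + rng.normal(0.0, sd, size=ph.size)
    ph = _clip_logged(ph, PH_MIN + 1e-6, PH_MAX - 1e-6, "pH")
    return pd.DataFrame({"x_cm": x, "y_cm": y, "ph_h2o": ph})


@dataclass
class SyntheticDepositionConfig:
    """Noise settings for synthetic deposition/seepage series."""

    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def generate_deposition_history(
    config: SyntheticDepositionConfig,
    scenario: DepositionScenario,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Annual (year, input_s, output_s) series for one column.

    With ``noise_sd`` 0 this is exactly the deterministic trajectory
    pair; otherwise independent Gaussian perturbations are added and
    clipped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    years = scenario.years
    inp = build_input_trajectory(scenario)
    out = build_output_trajectory(scenario)
    if config.noise_sd > 0:
        inp = np.maximum(inp + rng.normal(0.0, config.noise_sd, inp.size), 0.0)
        out = np.maximum(out + rng.normal(0.0, config.noise_sd, out.size), 0.0)
    return pd.DataFrame({"year": years, "input_s": inp, "output_s": out})


def survey_config_from_dict(raw: Mapping) -> SyntheticSurveyConfig:
    """Build a survey config from a plain mapping (e.g. a YAML section)."""
    known = {f.name for f in fields(SyntheticSurveyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown synthetic survey keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "horizons" in kwargs:
        kwargs["horizons"] = tuple(
            HorizonSpec(t, b) for t, b in kwargs["horizons"]
        )
    for name in ("sites", "distances_cm", "bulk_density", "depth_attenuation",
                 "depletion_weight", "c_conc_mg_g"):
        if name in kwargs:
            kwargs[name] = tuple(kwargs[name])
    if "recovered_horizon_counts" in kwargs:
        kwargs["recovered_horizon_counts"] = {
            float(k): int(v) for k, v in kwargs["recovered_horizon_counts"].items()
        }
    return SyntheticSurveyConfig(**kwargs)
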