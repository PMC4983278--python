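"""Micro-spatial soil chemistry gradients around a beech stem.

Operations on tidy soil-survey tables (one row per site x survey year x
distance x horizon, optionally x replicate):

* element stores (areal stocks, t ha-1) per horizon and per 0-50 cm
  profile,
* distance gradients with a monotonicity verdict,
* survey-to-survey temporal deltas (late minus early) per aligned cell,
* the acidification front: the depth above which pH has recovered since
  the early survey and below which it is still falling,
* inverse-distance-weighted (IDW) interpolation of grid pH samples.

Column schema of survey tables (see :mod:`stemsoil.io`): site,
survey_year, distance_cm, horizon_top_cm, horizon_bottom_cm, ph_h2o,
ca_exch_mg_g, mg_exch_mg_g, c_mg_g, n_mg_g, s_mg_g, bulk_density_g_cm3
[, stone_fraction, replicate].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .errors import (
    AlignmentError,
    AmbiguityError,
    HorizonError,
    IncompleteProfileError,
    StemsoilError,
)

log = logging.getLogger(__name__)

#: Tie tolerance for monotonicity verdicts, in the variable's own units.
GRADIENT_TIE_TOL = 1e-9
#: A query closer than this (cm) to a grid sample returns the sample value.
IDW_EXACT_HIT_CM = 1e-9

#: mg g-1 concentration column per element short name.
ELEMENT_COLUMNS: Mapping[str, str] = {
    "ca": "ca_exch_mg_g",
    "mg": "mg_exch_mg_g",
    "c": "c_mg_g",
    "n": "n_mg_g",
    "s": "s_mg_g",
}

_CELL_KEYS = ["site", "distance_cm", "horizon_top_cm", "horizon_bottom_cm"]


@dataclass(frozen=True, order=True)
class HorizonSpec:
    """Half-open mineral-soil depth interval [top, bottom) in cm, positive down."""

    top_cm: float
    bottom_cm: float

    def __post_init__(self) -> None:
        if not 0 <= self.top_cm < self.bottom_cm:
            raise HorizonError(
                f"need 0 <= top < bottom, got [{self.top_cm}, {self.bottom_cm})"
            )

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm


#: The canonical sampling design: five mineral horizons down to 50 cm ...
CANONICAL_HORIZONS: tuple[HorizonSpec, ...] = (
    HorizonSpec(0, 3),
    HorizonSpec(3, 10),
    HorizonSpec(10, 20),
    HorizonSpec(20, 30),
    HorizonSpec(30, 50),
)
#: ... at six distances from the trunk (negative = uphill).
CANONICAL_DISTANCES_CM: tuple[float, ...] = (-55.0, 27.0, 55.0, 100.0, 150.0, 300.0)


@dataclass(frozen=True)
class SurveyPair:
    """Aligned early and late surveys of the same sampling design."""

    early: pd.DataFrame
    late: pd.DataFrame

    def __post_init__(self) -> None:
        ey = self.early["survey_year"].unique()
        ly = self.late["survey_year"].unique()
        if len(ey) != 1 or len(ly) != 1:
            raise StemsoilError("each survey must hold exactly one survey_year")
        if ey[0] >= ly[0]:
            raise StemsoilError(
                f"early year {ey[0]} must precede late year {ly[0]}"
            )

    @property
    def early_year(self) -> int:
        return int(self.early["survey_year"].iloc[0])

    @property
    def late_year(self) -> int:
        return int(self.late["survey_year"].iloc[0])

    def swapped(self) -> "SurveyPair":
        """The reversed pair (used to check delta antisymmetry)."""
        early = self.late.assign(survey_year=self.early_year - 1)
        late = self.early.assign(survey_year=self.late_year)
        return SurveyPair(early=early, late=late)


def element_store(
    concentration_mg_g: float,
    bulk_density_g_cm3: float,
    horizon: HorizonSpec,
    stone_fraction: float = 0.0,
) -> float:
    """Areal element stock of one horizon, t ha-1.

    concentration (mg g-1) x bulk density (g cm-3) x thickness (cm) x 0.1
    converts to t ha-1; an optional coarse-fragment fraction scales the
    fine-earth volume by (1 - fraction).
    """
    if not 0 <= stone_fraction < 1:
        raise StemsoilError(f"stone_fraction must lie in [0, 1), got {stone_fraction}")
    return (
        concentration_mg_g
        * bulk_density_g_cm3
        * horizon.thickness_cm
        * 0.1
        * (1.0 - stone_fraction)
    )


def profile_store(
    samples: pd.DataFrame,
    elements: Sequence[str] = ("ca", "mg", "c", "n", "s"),
    horizons: Sequence[HorizonSpec] = CANONICAL_HORIZONS,
) -> dict[str, float]:
    """Per-element 0-50 cm stock (t ha-1) of one distance's depth profile.

    Requires one (replicate-averaged) sample per required horizon; a gap
    raises :class:`IncompleteProfileError` naming the missing horizons.
    """
    mean = samples.groupby(["horizon_top_cm", "horizon_bottom_cm"], as_index=False).mean(
        numeric_only=True
    )
    present = {
        HorizonSpec(t, b) for t, b in zip(mean["horizon_top_cm"], mean["horizon_bottom_cm"])
    }
    missing = [h for h in horizons if h not in present]
    if missing:
        raise IncompleteProfileError(
            [f"{h.top_cm:g}-{h.bottom_cm:g} cm" for h in missing]
        )
    stores = dict.fromkeys(elements, 0.0)
    for _, row in mean.iterrows():
        h = HorizonSpec(row["horizon_top_cm"], row["horizon_bottom_cm"])
        if h not in set(horizons):
            continue
        stone = float(row["stone_fraction"]) if "stone_fraction" in mean else 0.0
        for el in elements:
            stores[el] += element_store(
                row[ELEMENT_COLUMNS[el]], row["bulk_density_g_cm3"], h, stone
            )
    return stores


def survey_profile_stores(
    survey: pd.DataFrame,
    elements: Sequence[str] = ("ca", "mg", "c", "n", "s"),
    horizons: Sequence[HorizonSpec] = CANONICAL_HORIZONS,
) -> pd.DataFrame:
    """Tidy table of profile stores per (site, survey_year, distance, element)."""
    rows = []
    for (site, year, dist), grp in survey.groupby(
        ["site", "survey_year", "distance_cm"]
    ):
        stores = profile_store(grp, elements, horizons)
        for el, val in stores.items():
            rows.append(
                {
                    "site": site,
                    "survey_year": int(year),
                    "distance_cm": float(dist),
                    "element": el,
                    "store_t_ha": val,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GradientResult:
    """A downhill distance profile of one quantity plus a monotonicity verdict."""

    distances_cm: tuple[float, ...]
    values: tuple[float, ...]
    verdict: str
    uphill: tuple[tuple[float, float], ...] = ()


def distance_gradient(
    distances_cm: Sequence[float],
    values: Sequence[float],
    tol: float = GRADIENT_TIE_TOL,
) -> GradientResult:
    """Sort values by downhill distance and classify the trend.

    Uphill samples (distance < 0) are reported separately, not part of
    the verdict.  Verdicts use non-strict comparisons with an absolute
    tie tolerance; an all-flat profile is reported explicitly as
    'non-monotone: flat'.
    """
    d = np.asarray(distances_cm, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape:
        raise StemsoilError("distances and values must align")
    down = d > 0
    dd, vv = d[down], v[down]
    if np.unique(dd).size != dd.size:
        raise AmbiguityError("duplicate downhill distances")
    if dd.size < 3:
        raise StemsoilError("need at least 3 downhill distances for a gradient")
    order = np.argsort(dd)
    dd, vv = dd[order], vv[order]
    diffs = np.diff(vv)
    inc = bool(np.all(diffs >= -tol))
    dec = bool(np.all(diffs <= tol))
    if inc and dec:
        verdict = "non-monotone: flat"
    elif inc:
        verdict = "increasing"
    elif dec:
        verdict = "decreasing"
    else:
        verdict = "non-monotone"
    uphill = tuple((float(x), float(y)) for x, y in zip(d[~down], v[~down]))
    return GradientResult(
        distances_cm=tuple(float(x) for x in dd),
        values=tuple(float(x) for x in vv),
        verdict=verdict,
        uphill=uphill,
    )


def temporal_delta(pair: SurveyPair, variable: str) -> pd.DataFrame:
    """Per-cell late-minus-early differences of one variable.

    Replicates are averaged per (site, distance, horizon) cell first.
    Cells present in only one survey raise :class:`AlignmentError`.
    """
    def collapse(df: pd.DataFrame) -> pd.DataFrame:
        if variable not in df.columns:
            raise StemsoilError(f"unknown variable {variable!r}")
        sub = df.dropna(subset=[variable])
        n_dropped = len(df) - len(sub)
        if n_dropped:
            log.warning("dropped %d rows with missing %s", n_dropped, variable)
        return sub.groupby(_CELL_KEYS, as_index=False)[variable].mean()

    early = collapse(pair.early)
    late = collapse(pair.late)
    merged = early.merge(
        late, on=_CELL_KEYS, how="outer", suffixes=("_early", "_late"), indicator=True
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        raise AlignmentError(
            [tuple(r) for r in bad[_CELL_KEYS].itertuples(index=False)]
        )
    merged["delta"] = merged[f"{variable}_late"] - merged[f"{variable}_early"]
    out = merged[_CELL_KEYS + ["delta"]].sort_values(_CELL_KEYS).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class FrontResult:
    """Depth of the acidification front at one distance, if well defined.

    status: 'front' (sign change at depth_cm), 'surface' (whole profile
    still acidifying, front at 0 cm), 'no-front' (whole profile
    recovered), 'non-monotone' (delta signs alternate; flagged, absent).
    """

    depth_cm: float | None
    status: str


def acidification_front_depth(
    deltas: Sequence[float],
    horizons: Sequence[HorizonSpec] = CANONICAL_HORIZONS,
) -> FrontResult:
    """Locate the depth separating recovered (delta >= 0) from acidifying horizons.

    ``deltas`` are late-minus-early pH differences ordered by horizon top
    depth.  The front is the boundary between the deepest recovered
    horizon and the first deeper horizon with delta < 0, provided every
    deeper horizon is also acidifying.
    """
    if len(deltas) != len(horizons):
        raise HorizonError("one delta per horizon required")
    tops = [h.top_cm for h in horizons]
    if any(b <= a for a, b in zip(tops, tops[1:])):
        raise HorizonError("horizons must be ordered by increasing top depth")
    neg = [d < 0 for d in deltas]
    if not any(neg):
        return FrontResult(None, "no-front")
    if all(neg):
        return FrontResult(0.0, "surface")
    first_neg = neg.index(True)
    if all(neg[first_neg:]):
        return FrontResult(float(horizons[first_neg - 1].bottom_cm), "front")
    log.warning("non-monotone delta-pH sign pattern: %s", list(deltas))
    return FrontResult(None, "non-monotone")


def front_depth_table(pair: SurveyPair, variable: str = "ph_h2o") -> pd.DataFrame:
    """Acidification front per (site, distance) from a survey pair."""
    deltas = temporal_delta(pair, variable)
    rows = []
    for (site, dist), grp in deltas.groupby(["site", "distance_cm"]):
        grp = grp.sort_values("horizon_top_cm")
        horizons = [
            HorizonSpec(t, b)
            for t, b in zip(grp["horizon_top_cm"], grp["horizon_bottom_cm"])
        ]
        res = acidification_front_depth(list(grp["delta"]), horizons)
        rows.append(
            {
                "site": site,
                "distance_cm": float(dist),
                "front_depth_cm": res.depth_cm,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def idw_surface(
    sample_xy_cm: np.ndarray,
    sample_values: np.ndarray,
    query_xy_cm: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of scattered grid samples.

    All samples contribute (no search radius); a query within
    ``IDW_EXACT_HIT_CM`` of a sample returns that sample's value exactly.
    The result is a weighted mean, hence bounded by the sample range.
    """
    xy = np.atleast_2d(np.asarray(sample_xy_cm, dtype=float))
    vals = np.asarray(sample_values, dtype=float)
    q = np.atleast_2d(np.asarray(query_xy_cm, dtype=float))
    if xy.shape[0] == 0:
        raise StemsoilError("idw_surface requires at least one sample")
    if power <= 0:
        raise StemsoilError(f"power must be > 0, got {power}")
    dist = cdist(q, xy)
    out = np.empty(q.shape[0])
    hit = dist < IDW_EXACT_HIT_CM
    for i in range(q.shape[0]):
        if hit[i].any():
            out[i] = vals[np.argmax(hit[i])]
        else:
            w = dist[i] ** -power
            out[i] = np.sum(w * vals) / np.sum(w)
    return out


def log_distance_gradient_fit(
    survey: pd.DataFrame,
    survey_year: int,
    variable: str = "ph_h2o",
    horizon_top_cm: float = 0.0,
) -> tuple[float, float]:
    """OLS estimate of the downhill gradient amplitude and its standard error.

    Fits ``variable ~ ln(distance)`` over the downhill samples of one
    horizon and returns the fitted change between the nearest and the
    farthest sampled distance (the gradient amplitude) with its SE.
    """
    sub = survey[
        (survey["survey_year"] == survey_year)
        & (survey["horizon_top_cm"] == horizon_top_cm)
        & (survey["distance_cm"] > 0)
    ]
    if sub["distance_cm"].nunique() < 3:
        raise StemsoilError("need at least 3 downhill distances for the fit")
    x = np.log(sub["distance_cm"].to_numpy(dtype=float))
    y = sub[variable].to_numpy(dtype=float)
    fit = linregress(x, y)
    span = np.log(sub["distance_cm"].max() / sub["distance_cm"].min())
    return float(fit.slope * span), float(fit.stderr * span)
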