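"""Annual sulfur input/output trajectories and the recovery criterion.

The budget model is deliberately phenomenological.  For one soil column:

* the S **input** starts at the 1983 historic load, declines linearly to
  a measured 2013 anchor value, and is held constant afterwards
  (emissions had largely stabilized by then);
* the S **output** (seepage below the root zone) starts at the *maximal
  input* — steady state after a decade of roughly constant emissions —
  and holds that plateau for the column's steady-state ``delay`` before
  declining linearly to its own 2013 anchor; past the anchor it keeps
  the same slope until it meets the input line (or zero) and then tracks
  the input;
* **recovery** is the first year, strictly after the output plateau
  ends, in which annual output <= annual input (the column turns from a
  net S source into a net S sink).

All fluxes in kg S ha-1 yr-1 on the column's infiltration-area basis;
time in whole calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DelayError, ScenarioError, TrajectoryError

INPUT_AFTER_ANCHOR_MODES = ("constant", "extrapolate")
OUTPUT_AFTER_ANCHOR_MODES = ("track-input", "constant", "extrapolate")

STATUS_RECOVERED = "recovered-within-horizon"
STATUS_NOT_RECOVERED = "not-recovered"
STATUS_ALWAYS_BALANCED = "always-balanced"


@dataclass(frozen=True)
class DepositionScenario:
    """Endpoints and timing of one column's deposition history.

    ``load_1983`` is the column's local input at the start year (for a
    stemflow-fed column this is the TF plus concentrated SF flux);
    ``input_2013``/``output_2013`` are the anchor-year measurements.
    """

    load_1983: float
    input_2013: float
    output_2013: float
    delay_years: int
    start_year: int = 1983
    anchor_year: int = 2013
    horizon_year: int = 2050
    input_after_anchor: str = "constant"
    output_after_anchor: str = "track-input"

    def __post_init__(self) -> None:
        if not self.start_year < self.anchor_year < self.horizon_year:
            raise ScenarioError(
                f"need start < anchor < horizon, got {self.start_year}, "
                f"{self.anchor_year}, {self.horizon_year}"
            )
        for name in ("load_1983", "input_2013", "output_2013"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.delay_years < 0:
            raise DelayError("delay_years must be >= 0")
        if self.delay_years >= self.anchor_year - self.start_year:
            raise DelayError(
                f"delay {self.delay_years} must be shorter than the "
                f"{self.anchor_year - self.start_year}-year start-anchor span"
            )
        if self.input_after_anchor not in INPUT_AFTER_ANCHOR_MODES:
            raise ScenarioError(
                f"input_after_anchor must be one of {INPUT_AFTER_ANCHOR_MODES}"
            )
        if self.output_after_anchor not in OUTPUT_AFTER_ANCHOR_MODES:
            raise ScenarioError(
                f"output_after_anchor must be one of {OUTPUT_AFTER_ANCHOR_MODES}"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.horizon_year + 1)

    @property
    def plateau_end_year(self) -> int:
        return self.start_year + self.delay_years


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Paired annual S input and output series for one column."""

    years: np.ndarray
    input_s: np.ndarray
    output_s: np.ndarray
    plateau_end_year: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.years) == len(self.input_s) == len(self.output_s)):
            raise TrajectoryError("years, input_s and output_s must align")


class RecoveryScan(NamedTuple):
    year: int | None
    status: str


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of the recovery criterion for one column and one historic load."""

    column_distance_cm: float | None
    load_1983: float
    recovery_year: int | None
    status: str


def build_input_trajectory(scenario: DepositionScenario) -> np.ndarray:
    """Annual S input series: linear 1983->anchor, then constant (default)."""
    s = scenario
    years = s.years
    slope = (s.input_2013 - s.load_1983) / (s.anchor_year - s.start_year)
    line = s.load_1983 + slope * (years - s.start_year)
    if s.input_after_anchor == "constant":
        vals = np.where(years <= s.anchor_year, line, s.input_2013)
    else:  # extrapolate
        vals = line
    return np.maximum(vals, 0.0)


def build_output_trajectory(scenario: DepositionScenario) -> np.ndarray:
    """Annual S output series.

    Plateau at the maximal input (``load_1983``) through the steady-state
    delay, linear decline to the anchor measurement, then — in the
    default 'track-input' mode — the same slope until the series meets
    the input line or zero, following the input thereafter.
    """
    s = scenario
    years = s.years
    ps = s.plateau_end_year
    slope = (s.output_2013 - s.load_1983) / (s.anchor_year - ps)
    line = s.output_2013 + slope * (years - s.anchor_year)
    raw = np.where(years <= ps, s.load_1983, line)
    if s.output_after_anchor == "constant":
        raw = np.where(years <= s.anchor_year, raw, s.output_2013)
        return np.maximum(raw, 0.0)
    if s.output_after_anchor == "extrapolate":
        return np.maximum(raw, 0.0)
    # track-input: past the anchor the declining output cannot undershoot
    # the (non-negative) input line; once they meet, output follows input.
    inp = build_input_trajectory(s)
    out = np.maximum(raw, 0.0)
    after = years > s.anchor_year
    out[after] = np.maximum(raw[after], inp[after])
    return out


def build_trajectory(scenario: DepositionScenario) -> Trajectory:
    return Trajectory(
        years=scenario.years,
        input_s=build_input_trajectory(scenario),
        output_s=build_output_trajectory(scenario),
        plateau_end_year=scenario.plateau_end_year,
    )


def _plateau_end(traj: Trajectory) -> int:
    if traj.plateau_end_year is not None:
        return traj.plateau_end_year
    out = traj.output_s
    idx = 0
    while idx + 1 < len(out) and out[idx + 1] == out[0]:
        idx += 1
    return int(traj.years[idx])


def recovery_year(trajectory: Trajectory) -> RecoveryScan:
    """First year strictly after the output plateau with output <= input.

    Exact ties count as recovered.  A column whose output never exceeds
    its input is 'always-balanced' (reported at the start year); one that
    stays a net source through the horizon is 'not-recovered'.
    """
    if len(trajectory.years) == 0:
        raise TrajectoryError("empty trajectory")
    years = trajectory.years
    sink = trajectory.output_s <= trajectory.input_s
    if np.all(sink):
        return RecoveryScan(int(years[0]), STATUS_ALWAYS_BALANCED)
    candidates = sink & (years > _plateau_end(trajectory))
    hits = np.nonzero(candidates)[0]
    if hits.size == 0:
        return RecoveryScan(None, STATUS_NOT_RECOVERED)
    return RecoveryScan(int(years[hits[0]]), STATUS_RECOVERED)


def scenario_sweep(
    loads: Sequence[float],
    template: DepositionScenario,
    column_distance_cm: float | None = None,
) -> list[RecoveryResult]:
    """Recovery outcome for each historic 1983 load, template endpoints fixed."""
    if len(loads) == 0:
        raise ScenarioError("loads must be non-empty")
    results = []
    for load in loads:
        if load < template.input_2013:
            raise ScenarioError(
                f"load_1983 {load} below input_2013 {template.input_2013}: "
                "no historic decline to model"
            )
        scan = recovery_year(build_trajectory(replace(template, load_1983=load)))
        results.append(
            RecoveryResult(
                column_distance_cm=column_distance_cm,
                load_1983=float(load),
                recovery_year=scan.year,
                status=scan.status,
            )
        )
    return results


def cumulative_net_s(
    trajectory: Trajectory, from_year: int, to_year: int
) -> float:
    """Trapezoidal integral of (output - input) over [from_year, to_year].

    Positive values mean the column was a net S source over the interval,
    in kg S ha-1.
    """
    years = trajectory.years
    if from_year > to_year:
        raise TrajectoryError("from_year must be <= to_year")
    if from_year < years[0] or to_year > years[-1]:
        raise TrajectoryError(
            f"[{from_year}, {to_year}] outside trajectory range "
            f"[{years[0]}, {years[-1]}]"
        )
    i = int(np.searchsorted(years, from_year))
    j = int(np.searchsorted(years, to_year))
    net = trajectory.output_s - trajectory.input_s
    return float(np.trapezoid(net[i : j + 1], years[i : j + 1]))
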