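"""Trajectory construction, the recovery criterion and net-S mass balance.

The oracles here are deliberately independent of the implementation:
plain per-year two-point interpolation, an exhaustive annual scan, and a
dense midpoint Riemann sum.
"""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stemsoil as ss
from stemsoil.errors import DelayError, ScenarioError, TrajectoryError


# -- independent oracles ---------------------------------------------------

def oracle_input_value(sc, year):
    """Two-point linear interpolation, constant past the anchor."""
    if year <= sc.anchor_year:
        frac = (year - sc.start_year) / (sc.anchor_year - sc.start_year)
        v = sc.load_1983 + (sc.input_2013 - sc.load_1983) * frac
    else:
        v = sc.input_2013
    return max(v, 0.0)


def oracle_output_value(sc, year):
    """Plateau, two-point decline, then same slope bounded below by the input."""
    ps = sc.start_year + sc.delay_years
    if year <= ps:
        return sc.load_1983
    slope = (sc.output_2013 - sc.load_1983) / (sc.anchor_year - ps)
    v = sc.load_1983 + slope * (year - ps)
    if year <= sc.anchor_year:
        return max(v, 0.0)
    return max(v, oracle_input_value(sc, year), 0.0)


def oracle_recovery(sc):
    """Exhaustive year-by-year scan of the closed-form lines."""
    years = range(sc.start_year, sc.horizon_year + 1)
    if all(oracle_output_value(sc, y) <= oracle_input_value(sc, y) for y in years):
        return sc.start_year, "always-balanced"
    for y in years:
        if y <= sc.start_year + sc.delay_years:
            continue
        if oracle_output_value(sc, y) <= oracle_input_value(sc, y):
            return y, "recovered-within-horizon"
    return None, "not-recovered"


def random_scenarios(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        load = rng.uniform(5.0, 150.0)
        out.append(
            ss.DepositionScenario(
                load_1983=load,
                input_2013=rng.uniform(0.0, load),
                output_2013=rng.uniform(0.0, load),
                delay_years=int(rng.integers(0, 30)),
            )
        )
    return out


# -- input trajectory ------------------------------------------------------

class TestInputTrajectory:
    def test_no_decline_is_constant(self):
        sc = ss.DepositionScenario(115, 115, 115, 12)
        assert np.all(ss.build_input_trajectory(sc) == 115.0)

    def test_linear_midpoint(self):
        sc = ss.DepositionScenario(100, 10, 10, 12)
        traj = ss.build_trajectory(sc)
        assert traj.input_s[list(traj.years).index(1998)] == pytest.approx(55.0)

    def test_matches_interpolation_oracle_everywhere(self):
        sc = ss.DepositionScenario(15, 6, 6, 12)
        inp = ss.build_input_trajectory(sc)
        for y, v in zip(sc.years, inp):
            assert v == pytest.approx(oracle_input_value(sc, y), abs=1e-12)


# -- output trajectory -----------------------------------------------------

class TestOutputTrajectory:
    def test_degenerate_no_delay_shared_endpoints_equals_input(self):
        sc = ss.DepositionScenario(100, 10, 10, 0)
        assert np.allclose(
            ss.build_output_trajectory(sc), ss.build_input_trajectory(sc)
        )

    def test_plateau_holds_maximal_input(self):
        sc = ss.DepositionScenario(100, 10, 40, 12)
        traj = ss.build_trajectory(sc)
        inside = (traj.years >= 1983) & (traj.years <= 1995)
        assert np.all(traj.output_s[inside] == 100.0)

    def test_post_anchor_slope_hand_value(self):
        # slope after 1995 is (40-100)/18 per year; the line passes 70 at 2004
        sc = ss.DepositionScenario(100, 10, 40, 12)
        out = ss.build_output_trajectory(sc)
        assert out[list(sc.years).index(2004)] == pytest.approx(70.0)

    def test_delay_spanning_anchor_rejected(self):
        with pytest.raises(DelayError):
            ss.DepositionScenario(100, 10, 40, 30)

    def test_alternative_post_anchor_rules(self):
        base = ss.DepositionScenario(100, 10, 40, 12)
        const = dataclasses.replace(base, output_after_anchor="constant")
        extra = dataclasses.replace(
            base, output_after_anchor="extrapolate", horizon_year=2060
        )
        out_c = ss.build_output_trajectory(const)
        out_e = ss.build_output_trajectory(extra)
        after = const.years > 2013
        assert np.all(out_c[after] == 40.0)
        assert out_e[-1] == 0.0  # extrapolated line reaches the floor

    def test_segments_exactly_linear(self, default_scenario):
        """Second differences vanish within every linear segment."""
        traj = ss.build_trajectory(default_scenario)
        for series in (traj.input_s, traj.output_s):
            d2 = np.abs(np.diff(series, 2))
            # breakpoints: plateau end, anchor, input-line crossing
            assert np.sum(d2 > 1e-9) <= 3

    @given(st.integers(0, 199))
    def test_never_negative(self, idx):
        sc = random_scenarios(200, seed=901)[idx]
        assert np.all(ss.build_input_trajectory(sc) >= 0)
        assert np.all(ss.build_output_trajectory(sc) >= 0)


# -- recovery criterion ----------------------------------------------------

class TestRecoveryYear:
    def test_identity_always_balanced(self):
        sc = ss.DepositionScenario(100, 10, 10, 0)
        scan = ss.recovery_year(ss.build_trajectory(sc))
        assert scan == (1983, "always-balanced")

    def test_never_recovering_within_horizon(self):
        sc = ss.DepositionScenario(
            100, 6, 95, 12, output_after_anchor="extrapolate"
        )
        scan = ss.recovery_year(ss.build_trajectory(sc))
        assert scan.year is None and scan.status == "not-recovered"

    def test_agrees_with_exhaustive_scan(self):
        sc = ss.DepositionScenario(100, 10, 40, 12)
        scan = ss.recovery_year(ss.build_trajectory(sc))
        assert (scan.year, scan.status) == oracle_recovery(sc)

    def test_empty_trajectory_rejected(self):
        traj = ss.Trajectory(np.array([]), np.array([]), np.array([]))
        with pytest.raises(TrajectoryError):
            ss.recovery_year(traj)

    def test_plateau_end_inferred_without_metadata(self):
        sc = ss.DepositionScenario(100, 10, 40, 12)
        t = ss.build_trajectory(sc)
        bare = ss.Trajectory(t.years, t.input_s, t.output_s)  # no plateau hint
        assert ss.recovery_year(bare) == ss.recovery_year(t)


class TestScenarioSweep:
    def test_degenerate_load_recovers_at_start(self):
        tpl = ss.DepositionScenario(10, 10, 10, 12)
        (res,) = ss.scenario_sweep([10.0], tpl)
        assert res.recovery_year == 1983
        assert res.status == "always-balanced"

    def test_higher_load_never_recovers_earlier(self, default_scenario):
        results = ss.scenario_sweep([115, 55, 15], default_scenario)
        years = [r.recovery_year for r in results]
        assert years[0] >= years[1] >= years[2]

    def test_order_preserved(self, default_scenario):
        fwd = ss.scenario_sweep([115, 55, 15], default_scenario)
        rev = ss.scenario_sweep([15, 55, 115], default_scenario)
        assert [r.load_1983 for r in fwd] == [115, 55, 15]
        assert [r.recovery_year for r in rev] == [r.recovery_year for r in fwd][::-1]

    def test_load_below_anchor_input_rejected(self, default_scenario):
        with pytest.raises(ScenarioError):
            ss.scenario_sweep([5.0], default_scenario)


def test_chronosequence_smaller_delay_never_later(default_scenario):
    """Columns nearer the stem (smaller delay) recover no later."""
    years = []
    for delay in (4, 6, 7, 9, 12):
        sc = dataclasses.replace(default_scenario, delay_years=delay)
        years.append(ss.recovery_year(ss.build_trajectory(sc)).year)
    assert all(a <= b for a, b in zip(years, years[1:]))


# -- cumulative net S ------------------------------------------------------

class TestCumulativeNetS:
    def test_balanced_trajectory_integrates_to_zero(self):
        sc = ss.DepositionScenario(100, 10, 10, 0)
        traj = ss.build_trajectory(sc)
        assert ss.cumulative_net_s(traj, 1983, 2050) == pytest.approx(0.0)

    def test_constant_excess(self):
        years = np.arange(2000, 2011)
        traj = ss.Trajectory(years, np.full(11, 5.0), np.full(11, 7.0))
        assert ss.cumulative_net_s(traj, 2000, 2010) == pytest.approx(20.0)

    def test_range_errors(self, default_scenario):
        traj = ss.build_trajectory(default_scenario)
        with pytest.raises(TrajectoryError):
            ss.cumulative_net_s(traj, 1950, 2000)
        with pytest.raises(TrajectoryError):
            ss.cumulative_net_s(traj, 2000, 1990)

    def test_matches_dense_riemann_sum(self):
        """Trapezoid on annual nodes equals a 0.001-yr midpoint Riemann sum."""
        for sc in random_scenarios(5, seed=77):
            traj = ss.build_trajectory(sc)
            got = ss.cumulative_net_s(traj, sc.start_year, sc.horizon_year)
            dt = 0.001
            steps = (sc.horizon_year - sc.start_year) * 1000
            t = sc.start_year + (np.arange(steps) + 0.5) * dt
            net = np.interp(t, traj.years, traj.output_s - traj.input_s)
            assert got == pytest.approx(math.fsum(net) * dt, abs=1e-9)
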