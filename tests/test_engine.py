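"""Assembled system: integration accuracy, events, and trajectory metrics."""

import dataclasses
import math

import numpy as np
import pytest

from conjoint.engine import (
    ModelSpec,
    Trajectory,
    first_crossing_time,
    inhibition_onset_delay,
    peak,
    rhs,
    simulate,
    trajectory_distance,
)
from conjoint.errors import DomainError, EngineError
from conjoint.growth import GrowthLaw, closed_form_population
from conjoint.interactions import InteractionParams
from conjoint.pharmacology import DrugProgram
from conjoint.scenarios import get_preset

NORMAL = GrowthLaw(rate=0.4, capacity=1e6, shape=1.0)
TUMOR = GrowthLaw(rate=0.3, capacity=1.2e6, shape=1.0)
DECOUPLED = InteractionParams(beta=0.0, k=0.0, t_crit=3e5)
COUPLED = InteractionParams(beta=2.0, k=1.0, t_crit=3e5, rho0=1.0, rho1=1000.0)


def _spec(**kw):
    base = dict(
        normal_law=NORMAL,
        tumor_law=TUMOR,
        interaction=DECOUPLED,
        drug=DrugProgram(mode="none"),
        N0=1.0,
        T0=1.0,
        t_end=100.0,
    )
    base.update(kw)
    return ModelSpec(**base)


def _grid_trajectory(times, N, T):
    z = np.zeros_like(times)
    return Trajectory(times=times, N=N, T=T, u=z, kill_N=z, kill_T=z, segments=[])


class TestRhs:
    def test_joint_fixed_points(self):
        spec = _spec(interaction=COUPLED)
        assert rhs(0.0, NORMAL.capacity, 0.0, spec) == (0.0, 0.0)
        assert rhs(0.0, 0.0, 0.0, spec) == (0.0, 0.0)

    def test_coupled_untreated_flux_past_critical_size(self):
        # at (K_N, K_T): normal logistic flux 0, GMF inhibition dominates;
        # tumor logistic flux 0, suppression saturated near -k
        spec = _spec(interaction=COUPLED)
        dN, dT = rhs(0.0, 1e6, 1.2e6, spec)
        assert dN == pytest.approx(-5995004.163197336, rel=1e-9)
        assert dT == pytest.approx(-1.0, rel=1e-2)

    def test_decoupled_reduces_to_growth_laws(self):
        spec = _spec()
        dN, dT = rhs(0.0, 5e5, 6e5, spec)
        assert dN == pytest.approx(NORMAL.flux(5e5), rel=1e-14)
        assert dT == pytest.approx(TUMOR.flux(6e5), rel=1e-14)

    def test_invalid_states_rejected(self):
        spec = _spec()
        with pytest.raises(DomainError):
            rhs(0.0, -1.0, 1.0, spec)
        with pytest.raises(EngineError):
            rhs(0.0, float("nan"), 1.0, spec)


class TestSimulate:
    def test_decoupled_terminal_plateaus(self):
        traj = simulate(_spec(t_end=200.0))
        assert traj.N[-1] == pytest.approx(1e6, rel=1e-3)
        assert traj.T[-1] == pytest.approx(1.2e6, rel=1e-3)

    def test_extinction_is_absorbing(self):
        traj = simulate(_spec(N0=0.0, T0=0.0))
        assert np.all(traj.N == 0.0)
        assert np.all(traj.T == 0.0)

    def test_first_sample_is_initial_condition(self):
        traj = simulate(_spec())
        assert (traj.N[0], traj.T[0]) == (1.0, 1.0)
        assert np.all(np.diff(traj.times) > 0)

    @pytest.mark.parametrize("shape", [0.0, 1.0])
    def test_decoupled_matches_closed_forms(self, shape):
        """System-level oracle: the integrated decoupled paths equal the
        analytic logistic/Gompertz solutions."""
        tumor = GrowthLaw(rate=0.3 if shape else 0.083, capacity=1.2e6 if shape else 1e5, shape=shape)
        traj = simulate(_spec(tumor_law=tumor))
        expect_N = closed_form_population(NORMAL, 1.0, traj.times)
        expect_T = closed_form_population(tumor, 1.0, traj.times)
        np.testing.assert_allclose(traj.N, expect_N, rtol=1e-6)
        np.testing.assert_allclose(traj.T, expect_T, rtol=1e-6)

    def test_decoupled_logistic_tumor_crossing_time(self):
        traj = simulate(_spec())
        t_cross = first_crossing_time(traj, "T", 3e5)
        analytic = math.log((1.2e6 - 1) / 3) / 0.3
        assert t_cross == pytest.approx(analytic, abs=1e-4)
        assert t_cross == pytest.approx(43.0, abs=0.1)

    def test_zero_drug_matches_no_drug(self):
        none = simulate(_spec(interaction=COUPLED))
        zero = simulate(
            _spec(
                interaction=COUPLED,
                drug=DrugProgram(mode="static", u0=0.0, a_T=0.1, t_rx=40.0),
            )
        )
        np.testing.assert_allclose(zero.N, none.N, rtol=1e-7, atol=1e-8)
        np.testing.assert_allclose(zero.T, none.T, rtol=1e-7, atol=1e-8)

    def test_nonnegative_populations_everywhere(self):
        for drug in (
            DrugProgram(mode="none"),
            DrugProgram(mode="static", lumped_kill_N=0.1, lumped_kill_T=0.1, t_rx=40.0),
        ):
            traj = simulate(_spec(interaction=COUPLED, drug=drug))
            assert np.all(traj.N >= 0)
            assert np.all(traj.T >= 0)

    def test_grid_refinement_leaves_event_times_stable(self):
        coarse = simulate(_spec(interaction=COUPLED, dt=0.1))
        fine = simulate(_spec(interaction=COUPLED, dt=0.05))
        c1 = first_crossing_time(coarse, "T", 3e5)
        c2 = first_crossing_time(fine, "T", 3e5)
        assert abs(c1 - c2) < 1e-3
        p1, _ = peak(coarse, "N")
        p2, _ = peak(fine, "N")
        assert abs(p1 - p2) < 1e-3

    def test_monotone_therapy_effect_on_crossing(self):
        times = []
        for kill in (0.01, 0.05, 0.1):
            traj = simulate(
                _spec(
                    interaction=COUPLED,
                    drug=DrugProgram(
                        mode="static", lumped_kill_N=0.0, lumped_kill_T=kill, t_rx=40.0
                    ),
                )
            )
            times.append(first_crossing_time(traj, "T", 3e5))
        assert times[0] < times[1] < times[2]


class TestEvents:
    def test_crossing_on_closed_form_path_matches_analytic_half_time(self):
        times = np.linspace(0, 100, 1001)
        N = closed_form_population(NORMAL, 1.0, times)
        traj = _grid_trajectory(times, N, np.ones_like(times))
        t_half = first_crossing_time(traj, "N", NORMAL.capacity / 2)
        analytic = math.log(NORMAL.capacity / 1.0 - 1) / NORMAL.rate
        assert t_half == pytest.approx(analytic, abs=1e-3)

    def test_threshold_above_maximum_is_none(self):
        times = np.linspace(0, 10, 11)
        traj = _grid_trajectory(times, np.full(11, 5.0), np.full(11, 5.0))
        assert first_crossing_time(traj, "N", 10.0) is None

    def test_threshold_at_initial_value_is_first_time(self):
        times = np.linspace(0, 10, 11)
        traj = _grid_trajectory(times, np.full(11, 5.0), np.full(11, 5.0))
        assert first_crossing_time(traj, "N", 5.0) == 0.0

    def test_peak_of_monotone_path_is_terminal(self):
        times = np.linspace(0, 10, 101)
        traj = _grid_trajectory(times, times**2, np.zeros_like(times))
        t, v = peak(traj, "N")
        assert t == pytest.approx(10.0, abs=1e-6)
        assert v == pytest.approx(100.0, rel=1e-6)

    def test_peak_of_constant_path_is_earliest(self):
        times = np.linspace(0, 10, 11)
        traj = _grid_trajectory(times, np.full(11, 3.0), np.zeros(11))
        assert peak(traj, "N") == (0.0, 3.0)

    def test_interior_peak_refined(self):
        times = np.linspace(0, 10, 101)
        N = -((times - 4.321) ** 2) + 50.0
        traj = _grid_trajectory(times, N, np.zeros_like(times))
        t, v = peak(traj, "N")
        assert t == pytest.approx(4.321, abs=0.06)  # linear-interp refinement
        assert v == pytest.approx(50.0, rel=1e-3)


class TestComparativeMetrics:
    def test_identical_trajectories_have_zero_delay_and_distance(self):
        traj = simulate(_spec(interaction=COUPLED))
        assert inhibition_onset_delay(traj, traj) == 0.0
        assert trajectory_distance(traj, traj) == 0.0

    def test_overwhelming_kill_censors_the_delay(self):
        untreated = simulate(_spec(interaction=COUPLED))
        crushed = simulate(
            _spec(
                interaction=COUPLED,
                drug=DrugProgram(
                    mode="static", lumped_kill_N=0.0, lumped_kill_T=1.0, t_rx=40.0
                ),
            )
        )
        # the tumor is held below the critical size for the whole horizon,
        # so the inhibition regime is never entered: onset censored
        assert math.isinf(inhibition_onset_delay(crushed, untreated, t_crit=3e5))

    def test_distance_symmetric_and_grid_checked(self):
        a = simulate(_spec(interaction=COUPLED))
        b = simulate(
            _spec(
                interaction=COUPLED,
                drug=DrugProgram(
                    mode="static", lumped_kill_N=0.0, lumped_kill_T=0.1, t_rx=40.0
                ),
            )
        )
        assert trajectory_distance(a, b) == trajectory_distance(b, a) > 0
        short = simulate(_spec(interaction=COUPLED, t_end=50.0))
        with pytest.raises(DomainError):
            trajectory_distance(a, short)

    def test_therapy_trigger_at_critical_size(self):
        """Size-triggered therapy starts the drug at the T* crossing."""
        spec = _spec(
            interaction=COUPLED,
            drug=DrugProgram(mode="static", lumped_kill_N=0.0, lumped_kill_T=0.1, t_rx=0.0),
            therapy_trigger="tumor_exceeds_tcrit",
        )
        traj = simulate(spec)
        untreated = simulate(_spec(interaction=COUPLED))
        cross = first_crossing_time(untreated, "T", 3e5)
        # no kill before the crossing, kill active after
        before = traj.times < cross
        assert np.all(traj.kill_T[before] == 0.0)
        assert traj.kill_T[-1] == pytest.approx(0.1)
        np.testing.assert_allclose(traj.T[before], untreated.T[before], rtol=1e-6)
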