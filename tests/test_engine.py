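import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctlsim.agents import Mode, Phase
from ctlsim.engine import add_ctl_cohort, initialize_well, run_simulation
from ctlsim.params import (
    ConfigurationError,
    ParameterError,
    default_simulation_params,
)

from conftest import make_pinned_params, make_pinned_world


class TestInitializeWell:
    def test_counts_and_types(self, small_params):
        world = initialize_well(small_params)
        assert len(world.targets) == 40
        assert len(world.ctls) == 20
        assert all(c.mode is Mode.SEARCH for c in world.ctls)

    def test_et_ratio_one_creates_equal_ctl(self):
        p = default_simulation_params(initial_targets=100, et_ratio=1.0, duration=60.0)
        world = initialize_well(p)
        assert len(world.ctls) == 100

    def test_zero_ctl_world(self):
        p = default_simulation_params(initial_targets=10, initial_ctl=0, duration=60.0)
        world = initialize_well(p)
        assert len(world.ctls) == 0 and len(world.targets) == 10

    def test_central_aggregation(self, small_params):
        world = initialize_well(small_params)
        m = small_params.mechanics
        cross = (
            len(world.targets) * m.target_radius**2 + len(world.ctls) * m.ctl_radius**2
        )
        disc_r = math.sqrt(1.3 * cross)
        for agent in [*world.targets, *world.ctls]:
            # relaxation may push slightly beyond the seeding disc
            assert np.linalg.norm(agent.position) < disc_r + 6 * m.target_radius

    def test_no_residual_overlap_beyond_tolerance(self, small_params):
        world = initialize_well(small_params)
        agents = [*world.targets, *world.ctls]
        for i in range(len(agents)):
            for j in range(i + 1, len(agents)):
                d = np.linalg.norm(agents[i].position - agents[j].position)
                rsum = agents[i].radius + agents[j].radius
                assert rsum - d <= small_params.mechanics.contact_tolerance * rsum + 1e-6

    def test_same_seed_identical(self, small_params):
        w1 = initialize_well(small_params)
        w2 = initialize_well(small_params)
        for a, b in zip(w1.targets, w2.targets):
            assert np.array_equal(a.position, b.position)
        for a, b in zip(w1.ctls, w2.ctls):
            assert np.array_equal(a.position, b.position)

    def test_overfull_well_rejected(self):
        p = default_simulation_params(
            initial_targets=400, initial_ctl=0, duration=60.0
        )
        p = dataclasses.replace(
            p, mechanics=dataclasses.replace(p.mechanics, well_radius=100.0)
        )
        with pytest.raises(ConfigurationError, match="fit"):
            initialize_well(p)


class TestRunSimulation:
    def test_duration_zero_single_snapshot(self, small_params):
        p = dataclasses.replace(small_params, duration=0.0)
        result = run_simulation(p, seed=3)
        assert len(result.times) == 1
        assert result.live_targets[0] == 40
        assert result.total_deaths == 0

    def test_pinned_death_time_oracle(self):
        # 1 CTL adjacent to 1 target, no motility, no disabling:
        # death at exactly ceil(S / dt) steps, i.e. t = S
        p = make_pinned_params(survival=300.0, dt=0.5, duration=400.0)
        world = make_pinned_world(p, [(0.0, 0.0)], [(13.0, 0.0)])
        result = run_simulation(p, initial_world=world, seed=0)
        deaths = [e for e in result.events if e.kind.value == "DEATH"]
        assert len(deaths) == 1
        assert deaths[0].time == pytest.approx(300.0)
        assert result.kill_frac.sum() == pytest.approx(1.0)
        assert result.kill_int.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3])
    def test_pinned_shared_kill_time(self, k):
        # k attackers: death at S/k within one step
        p = make_pinned_params(survival=300.0, dt=0.5, duration=400.0)
        angles = np.linspace(0, 2 * math.pi, k, endpoint=False)
        ctls = [(13.0 * math.cos(a), 13.0 * math.sin(a)) for a in angles]
        world = make_pinned_world(p, [(0.0, 0.0)], ctls)
        result = run_simulation(p, initial_world=world, seed=0)
        deaths = [e for e in result.events if e.kind.value == "DEATH"]
        assert len(deaths) == 1
        assert abs(deaths[0].time - 300.0 / k) <= 0.5 + 1e-9
        # fractional credit shared equally
        assert np.allclose(result.kill_frac, 1.0 / k)
        assert result.kill_int.sum() == pytest.approx(1.0)

    def test_conservation_and_partition(self, small_params):
        p = dataclasses.replace(small_params, duration=360.0)
        result = run_simulation(p, seed=11)
        assert np.array_equal(
            result.live_targets,
            result.initial_targets + result.cum_divisions - result.cum_deaths,
        )
        assert np.array_equal(
            result.ctl_total,
            result.ctl_search + result.ctl_attack + result.ctl_disabled,
        )

    def test_bit_identical_reproducibility(self, small_params):
        r1 = run_simulation(small_params, seed=5)
        r2 = run_simulation(small_params, seed=5)
        for name in ("times", "live_targets", "cum_deaths", "cum_divisions", "kill_frac", "kill_int"):
            assert np.array_equal(getattr(r1, name), getattr(r2, name)), name
        assert [(e.kind, e.time, e.agent_id) for e in r1.events] == [
            (e.kind, e.time, e.agent_id) for e in r2.events
        ]

    def test_kill_ledgers_sum_to_deaths(self, small_params):
        p = dataclasses.replace(small_params, duration=480.0)
        result = run_simulation(p, seed=2)
        assert result.total_deaths > 0
        assert result.kill_frac.sum() == pytest.approx(result.total_deaths)
        assert result.kill_int.sum() == pytest.approx(result.total_deaths)

    def test_pd_zero_no_disabled_ever(self, small_params):
        killing = dataclasses.replace(small_params.killing, disabling_probability=0.0)
        p = dataclasses.replace(small_params, killing=killing, duration=240.0)
        result = run_simulation(p, seed=4)
        assert np.all(result.ctl_disabled == 0)

    def test_population_cap_truncates_with_escaped_flag(self):
        p = default_simulation_params(
            "melanoma",
            initial_targets=30,
            initial_ctl=0,
            duration=7200.0,
            population_cap=60,
        )
        result = run_simulation(p, seed=9)
        assert result.escaped
        assert result.times[-1] < 7200.0

    def test_cohort_schedule_applied(self):
        p = default_simulation_params(
            "melanoma",
            initial_targets=20,
            initial_ctl=5,
            duration=120.0,
            cohort_schedule=((60.0, 7),),
            recording_interval=15.0,
        )
        result = run_simulation(p, seed=1)
        assert result.ctl_total[0] == 5
        assert result.ctl_total[-1] == 12
        before = result.ctl_total[result.times < 60.0]
        assert np.all(before == 5)

    def test_step_size_robustness_with_hazard_rescaling(self):
        # halving dt (P_d rescaled through reference_dt) leaves mean kill
        # counts nearly unchanged; scaled-down version of the spec's check
        means = {}
        for dt in (1.0, 0.5):
            p = default_simulation_params(
                "melanoma", initial_targets=150, et_ratio=1.0, duration=1080.0, dt=dt
            )
            kills = [run_simulation(p, seed=100 + i).total_deaths for i in range(20)]
            means[dt] = np.mean(kills)
        assert abs(means[1.0] - means[0.5]) / means[0.5] < 0.05


class TestAddCtlCohort:
    def test_adds_search_ctl(self, small_params):
        world = initialize_well(small_params)
        rng = np.random.default_rng(8)
        bigger = add_ctl_cohort(world, 50, small_params, rng)
        assert len(bigger.ctls) == 70
        assert sum(c.mode is Mode.SEARCH for c in bigger.ctls) >= 50
        assert len(bigger.targets) == len(world.targets)

    def test_zero_cohort_rejected(self, small_params):
        world = initialize_well(small_params)
        with pytest.raises(ParameterError):
            add_ctl_cohort(world, 0, small_params)

    def test_same_seed_identical_placement(self, small_params):
        world = initialize_well(small_params)
        a = add_ctl_cohort(world, 10, small_params, np.random.default_rng(3))
        b = add_ctl_cohort(world, 10, small_params, np.random.default_rng(3))
        for ca, cb in zip(a.ctls, b.ctls):
            assert np.array_equal(ca.position, cb.position)


class TestGrowth:
    def test_zero_ctl_exponential_growth(self):
        # closed form N0 * 2^(t/Tc) over 48 h, mean of 5 runs
        p = default_simulation_params(
            "melanoma", initial_targets=50, initial_ctl=0, duration=2880.0
        )
        tc = p.cycle.total_mean
        finals = [run_simulation(p, seed=200 + i).final_live_targets for i in range(5)]
        expected = 50 * 2 ** (2880.0 / tc)
        assert np.mean(finals) == pytest.approx(expected, rel=0.12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=5, deadline=None)
    def test_disabled_absorbing_over_random_runs(self, seed):
        p = default_simulation_params(
            "melanoma", initial_targets=30, et_ratio=1.0, duration=240.0,
            recording_interval=15.0,
        )
        result = run_simulation(p, seed=seed)
        assert np.all(np.diff(result.ctl_disabled) >= 0)
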