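import math

import numpy as np
import pytest
from scipy import stats

from ctlsim.agents import (
    AdhesionBond,
    CtlState,
    EventKind,
    Mode,
    Phase,
    StateError,
    divide_target,
    draw_phase_durations,
    update_ctl,
    update_target,
)
from ctlsim.params import CyclePhaseParams, KillingParams, ParameterError

from conftest import make_ctl, make_pinned_params, make_target


class TestDrawPhaseDurations:
    def test_degenerate_normal_is_exact(self, rng):
        cyc = CyclePhaseParams(g1s_mean=600.0, g1s_sd=0.0, g2m_mean=240.0, g2m_sd=0.0)
        assert draw_phase_durations(cyc, rng) == (600.0, 240.0)

    def test_sample_mean_matches(self, rng):
        cyc = CyclePhaseParams(g1s_mean=600.0, g1s_sd=60.0, g2m_mean=240.0, g2m_sd=0.0)
        draws = np.array([draw_phase_durations(cyc, rng)[0] for _ in range(10_000)])
        se = 60.0 / math.sqrt(len(draws))
        assert abs(draws.mean() - 600.0) < 3 * se

    def test_truncation_strictly_positive(self, rng):
        # sd much larger than mean: naive normal would go negative often
        cyc = CyclePhaseParams(g1s_mean=60.0, g1s_sd=300.0, g2m_mean=60.0, g2m_sd=300.0)
        draws = [draw_phase_durations(cyc, rng) for _ in range(10_000)]
        assert all(g1 > 0 and g2 > 0 for g1, g2 in draws)


class TestUpdateTarget:
    def setup_method(self):
        self.p = make_pinned_params(survival=300.0, dt=0.5)
        self.killing = self.p.killing

    def test_cycling_timer_decrement_only(self, rng):
        cell = make_target("t0", (0, 0), self.p)
        t0 = cell.phase_time_remaining
        cell, events = update_target(cell, [], self.killing, dt=0.5)
        assert cell.phase is Phase.G1S
        assert cell.phase_time_remaining == t0 - 0.5
        assert events == []
        assert cell.survival_remaining == 300.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_death_time_closed_form(self, k):
        # S / k rule: death after exactly ceil(S / (k dt)) steps
        cell = make_target("t0", (0, 0), self.p)
        attackers = [
            make_ctl(f"c{j}", (16, 0), self.p, mode=Mode.ATTACK, bonded="t0")
            for j in range(k)
        ]
        steps = 0
        while cell.phase is not Phase.DEAD:
            cell, events = update_target(cell, attackers, self.killing, dt=0.5)
            steps += 1
            assert steps < 10_000
        assert steps == math.ceil(300.0 / (k * 0.5))
        assert any(e.kind is EventKind.DEATH for e in events)

    def test_defense_freezes_cycle_and_reverts(self):
        cell = make_target("t0", (0, 0), self.p)
        timer0 = cell.phase_time_remaining
        attacker = make_ctl("c0", (16, 0), self.p, mode=Mode.ATTACK, bonded="t0")
        for _ in range(100):
            cell, _ = update_target(cell, [attacker], self.killing, dt=0.5)
        assert cell.phase is Phase.DEFENSE
        assert cell.phase_time_remaining == timer0  # frozen
        assert cell.survival_remaining == pytest.approx(250.0)  # 300 - 100 * 0.5
        # all attackers gone: revert to stored phase, survival persists
        cell, _ = update_target(cell, [], self.killing, dt=0.5)
        assert cell.phase is Phase.G1S
        assert cell.survival_remaining == pytest.approx(250.0)

    def test_inactive_ctl_do_not_attack(self):
        cell = make_target("t0", (0, 0), self.p)
        lurker = make_ctl("c0", (16, 0), self.p, mode=Mode.SEARCH)
        cell, _ = update_target(cell, [lurker], self.killing, dt=0.5)
        assert cell.phase is Phase.G1S
        assert cell.survival_remaining == 300.0

    def test_division_event_at_g2m_expiry(self):
        cell = make_target("t0", (0, 0), self.p)
        cell.phase = Phase.G2M
        cell.g2m_duration = 1.0
        cell.phase_time_remaining = 1.0
        cell, events = update_target(cell, [], self.killing, dt=0.5)
        assert cell.mass == pytest.approx(1.5)
        cell, events = update_target(cell, [], self.killing, dt=0.5)
        assert any(e.kind is EventKind.DIVISION for e in events)
        assert cell.mass == pytest.approx(2.0)

    def test_dt_nonpositive_rejected(self):
        cell = make_target("t0", (0, 0), self.p)
        with pytest.raises(ParameterError):
            update_target(cell, [], self.killing, dt=0.0)

    def test_dead_cell_rejected(self):
        cell = make_target("t0", (0, 0), self.p)
        cell.phase = Phase.DEAD
        with pytest.raises(StateError):
            update_target(cell, [], self.killing, dt=0.5)


class TestUpdateCtl:
    def setup_method(self):
        self.p = make_pinned_params(survival=300.0, dt=0.5)

    def test_pd_zero_never_disables(self, rng):
        killing = KillingParams(300.0, 100.0, 0.0, 0.5)
        ctl = make_ctl("c0", (0, 0), self.p)
        for _ in range(2000):
            ctl, _ = update_ctl(ctl, [], 5, killing, 0.5, rng)
        assert ctl.mode is Mode.SEARCH

    def test_search_with_no_contacts_stays_search(self, rng):
        killing = KillingParams(300.0, 100.0, 0.001, 0.5)
        ctl = make_ctl("c0", (0, 0), self.p)
        ctl, events = update_ctl(ctl, [], 0, killing, 0.5, rng)
        assert ctl.mode is Mode.SEARCH and events == []

    def test_contact_triggers_attack_bond(self, rng):
        killing = KillingParams(300.0, 100.0, 0.0, 0.5)
        target = make_target("t0", (10, 0), self.p)
        ctl = make_ctl("c0", (0, 0), self.p)
        ctl, events = update_ctl(ctl, [target], 0, killing, 0.5, rng)
        assert ctl.mode is Mode.ATTACK
        assert ctl.bonded_target_id == "t0"
        assert events[0].kind is EventKind.BOND

    def test_geometric_mean_steps_to_disable(self, rng):
        # mean steps to disable = 1 / P_d (geometric law); P_d scaled up
        # from the spec's 0.00025 so the scalar-update loop stays fast
        p_d = 0.02
        killing = KillingParams(300.0, 100.0, p_d, 0.5)
        steps = []
        for _ in range(5000):
            ctl = make_ctl("c0", (0, 0), self.p)
            n = 0
            while ctl.mode is not Mode.DISABLED:
                ctl, _ = update_ctl(ctl, [], 1, killing, 0.5, rng)
                n += 1
            steps.append(n)
        assert np.mean(steps) == pytest.approx(1.0 / p_d, rel=0.05)

    def test_disabled_is_absorbing(self, rng):
        killing = KillingParams(300.0, 100.0, 1.0, 0.5)
        target = make_target("t0", (10, 0), self.p)
        ctl = make_ctl("c0", (0, 0), self.p)
        ctl, events = update_ctl(ctl, [target], 1, killing, 0.5, rng)
        assert ctl.mode is Mode.DISABLED
        assert ctl.bonded_target_id is None
        kinds = [e.kind for e in events]
        assert EventKind.DISABLE in kinds and EventKind.UNBOND in kinds
        for _ in range(100):
            ctl, events = update_ctl(ctl, [target], 1, killing, 0.5, rng)
            assert ctl.mode is Mode.DISABLED and events == []

    def test_per_target_draw_inflates_hazard(self, rng):
        killing = KillingParams(300.0, 100.0, 0.01, 0.5)
        hits = {mode: 0 for mode in ("per_ctl", "per_target")}
        for mode in hits:
            for _ in range(2000):
                ctl = make_ctl("c0", (0, 0), self.p)
                ctl, _ = update_ctl(
                    ctl, [], 10, killing, 0.5, rng, disabling_draw=mode
                )
                if ctl.mode is Mode.DISABLED:
                    hits[mode] += 1
        assert hits["per_target"] > 5 * hits["per_ctl"]


class TestDivideTarget:
    def setup_method(self):
        self.p = make_pinned_params()
        self.cyc = CyclePhaseParams(g1s_mean=600.0, g1s_sd=0.0, g2m_mean=240.0, g2m_sd=0.0)

    def _ripe_mother(self):
        cell = make_target("t0", (5.0, -3.0), self.p)
        cell.phase = Phase.G2M
        cell.phase_time_remaining = 0.0
        cell.mass = 2.0
        return cell

    def test_bookkeeping(self, rng):
        mother, daughter = divide_target(self._ripe_mother(), self.cyc, rng, "t1")
        assert mother.mass == 1.0 and daughter.mass == 1.0
        assert mother.phase is Phase.G1S and daughter.phase is Phase.G1S
        assert daughter.line == mother.line and daughter.radius == mother.radius
        d = np.linalg.norm(daughter.position - mother.position)
        assert d == pytest.approx(2 * mother.radius)

    def test_daughter_gets_full_survival_budget(self, rng):
        mother = self._ripe_mother()
        mother.survival_remaining = 100.0
        mother, daughter = divide_target(mother, self.cyc, rng, "t1")
        assert daughter.survival_remaining == daughter.survival_total

    def test_wrong_phase_rejected(self, rng):
        cell = make_target("t0", (0, 0), self.p)
        with pytest.raises(StateError):
            divide_target(cell, self.cyc, rng, "t1")

    def test_division_angles_uniform(self, rng):
        angles = []
        for i in range(10_000):
            mother, daughter = divide_target(self._ripe_mother(), self.cyc, rng, "t1")
            delta = daughter.position - mother.position
            angles.append(math.atan2(delta[1], delta[0]) % (2 * math.pi))
        counts, _ = np.histogram(angles, bins=12, range=(0, 2 * math.pi))
        assert stats.chisquare(counts).pvalue > 1e-3


def test_bond_invariants():
    with pytest.raises(StateError):
        AdhesionBond("t0", "t0", 16.0)
    with pytest.raises(StateError):
        AdhesionBond("c0", "c1", 10.0)  # CTL never adhere to each other


def test_ctl_state_bond_consistency():
    with pytest.raises(StateError):
        CtlState(id="c0", position=np.zeros(2), radius=5.0, mode=Mode.ATTACK)
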