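"""World construction and the main simulation loop.

The engine advances the co-culture in fixed steps of ``dt`` minutes.  Each
step: (1) detect contacts and form adhesion bonds, (2) update all target
cells (defense, survival depletion, death, cycling, division),
(3) update all CTL (disabling draws), (4) apply scheduled CTL cohort
additions, (5) integrate mechanics, (6) record statistics.

Internally the population lives in flat numpy arrays (struct-of-arrays)
for speed; :class:`WellState` record snapshots are materialised at the API
boundary.  The per-agent reference semantics live in :mod:`ctlsim.agents`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import mechanics as mech
from .agents import (
    AdhesionBond,
    CtlState,
    Event,
    EventKind,
    Mode,
    Phase,
    TargetCellState,
    truncated_normal,
)
from .params import ConfigurationError, ParameterError, SimulationParams

__all__ = [
    "WellState",
    "RunResult",
    "initialize_well",
    "run_simulation",
    "add_ctl_cohort",
]

# integer phase/mode codes used by the array core
_G1S, _G2M, _DEFENSE = 0, 1, 2
_SEARCH, _ATTACK, _DISABLED = 0, 1, 2

_PHASE_TO_CODE = {Phase.G1S: _G1S, Phase.G2M: _G2M, Phase.DEFENSE: _DEFENSE}
_CODE_TO_PHASE = {v: k for k, v in _PHASE_TO_CODE.items()}
_MODE_TO_CODE = {Mode.SEARCH: _SEARCH, Mode.ATTACK: _ATTACK, Mode.DISABLED: _DISABLED}
_CODE_TO_MODE = {v: k for k, v in _MODE_TO_CODE.items()}

_KEY = 1 << 21  # packing base for target-target bond keys


@dataclass
class WellState:
    """Full record-level simulation world at one instant."""

    clock: float
    targets: List[TargetCellState]
    ctls: List[CtlState]
    bonds: List[AdhesionBond]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.targets] + [c.id for c in self.ctls]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("agent ids must be unique")
        live = set(ids)
        for bond in self.bonds:
            if bond.agent_a_id not in live or bond.agent_b_id not in live:
                raise ConfigurationError(
                    f"bond ({bond.agent_a_id}, {bond.agent_b_id}) references a missing agent"
                )


@dataclass
class RunResult:
    """Time series of population counts plus the per-CTL kill ledger."""

    times: np.ndarray  # minutes, one entry per recording
    live_targets: np.ndarray
    cum_deaths: np.ndarray
    cum_divisions: np.ndarray
    ctl_search: np.ndarray
    ctl_attack: np.ndarray
    ctl_disabled: np.ndarray
    ctl_total: np.ndarray
    per_capita: np.ndarray  # cumulative kills / CTL present, nan if none
    ctl_ids: List[str]
    kill_frac: np.ndarray  # fractional-credit ledger (sums to deaths)
    kill_int: np.ndarray  # integer-credit ledger (longest-attached attacker)
    events: List[Event]
    seed: object
    params_digest: str
    initial_targets: int
    escaped: bool
    final_world: WellState

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times / 60.0,
                "live_targets": self.live_targets,
                "cum_deaths": self.cum_deaths,
                "cum_divisions": self.cum_divisions,
                "ctl_search": self.ctl_search,
                "ctl_attack": self.ctl_attack,
                "ctl_disabled": self.ctl_disabled,
                "ctl_total": self.ctl_total,
                "per_capita": self.per_capita,
            }
        )

    @property
    def final_live_targets(self) -> int:
        return int(self.live_targets[-1])

    @property
    def total_deaths(self) -> int:
        return int(self.cum_deaths[-1])


class _Sim:
    """Array-backed simulation state."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.p = params
        self.m = params.mechanics
        self.rng = rng
        self.clock = 0.0
        self.cum_deaths = 0
        self.cum_divisions = 0
        self.events: List[Event] = []
        self._schedule = list(params.cohort_schedule)
        self._sched_idx = 0
        self.escaped = False
        cap_t = max(64, 2 * params.initial_targets + 16)
        cap_c = max(16, 2 * (params.n_initial_ctl + sum(n for _, n in self._schedule)) + 8)
        self.n_t = 0
        self.n_c = 0
        self._alloc_targets(cap_t)
        self._alloc_ctls(cap_c)
        self.tt_keys = np.zeros(0, dtype=np.int64)  # sorted packed bond keys

    # -- storage ------------------------------------------------------------

    def _alloc_targets(self, cap: int) -> None:
        self.t_pos = np.zeros((cap, 2))
        self.t_alive = np.zeros(cap, dtype=bool)
        self.t_phase = np.zeros(cap, dtype=np.int8)
        self.t_stored = np.zeros(cap, dtype=np.int8)
        self.t_tleft = np.zeros(cap)
        self.t_g2m = np.ones(cap)
        self.t_surv = np.zeros(cap)

    def _grow_targets(self) -> None:
        cap = len(self.t_alive)
        for name in ("t_pos", "t_alive", "t_phase", "t_stored", "t_tleft", "t_g2m", "t_surv"):
            arr = getattr(self, name)
            shape = (2 * cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            if name == "t_g2m":
                new[:] = 1.0
            new[: len(arr)] = arr
            setattr(self, name, new)

    def _alloc_ctls(self, cap: int) -> None:
        self.c_pos = np.zeros((cap, 2))
        self.c_mode = np.zeros(cap, dtype=np.int8)
        self.c_bond = np.full(cap, -1, dtype=np.int64)
        self.c_bond_t = np.zeros(cap)
        self.c_kill_frac = np.zeros(cap)
        self.c_kill_int = np.zeros(cap)

    def _grow_ctls(self, need: int) -> None:
        cap = len(self.c_mode)
        new_cap = max(2 * cap, self.n_c + need)
        for name in ("c_pos", "c_mode", "c_bond", "c_bond_t", "c_kill_frac", "c_kill_int"):
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            if name == "c_bond":
                new[:] = -1
            new[: len(arr)] = arr
            setattr(self, name, new)

    # -- construction -------------------------------------------------------

    @classmethod
    def fresh(cls, params: SimulationParams, rng: np.random.Generator) -> "_Sim":
        sim = cls(params, rng)
        n_t, n_c = params.initial_targets, params.n_initial_ctl
        sim._spawn_targets_steady_state(n_t)
        sim._append_ctls(np.zeros((n_c, 2)))
        total = n_t + n_c
        if total:
            positions = sim._centrifuge_positions(
                n_t * sim.m.target_radius**2 + n_c * sim.m.ctl_radius**2, total
            )
            order = rng.permutation(total)
            positions = positions[order]
            sim.t_pos[:n_t] = positions[:n_t]
            sim.c_pos[:n_c] = positions[n_t:]
            sim._relax_world()
        return sim

    @classmethod
    def from_world(
        cls, world: WellState, params: SimulationParams, rng: np.random.Generator
    ) -> "_Sim":
        sim = cls(params, rng)
        sim.clock = world.clock
        n_t, n_c = len(world.targets), len(world.ctls)
        while len(sim.t_alive) < n_t + 8:
            sim._grow_targets()
        if len(sim.c_mode) < n_c + 8:
            sim._grow_ctls(n_c + 8)
        sim.t_ids = [t.id for t in world.targets]
        sim.c_ids = [c.id for c in world.ctls]
        tid_to_slot = {t.id: i for i, t in enumerate(world.targets)}
        for i, t in enumerate(world.targets):
            if t.phase is Phase.DEAD:
                raise ConfigurationError("cannot build a world containing dead targets")
            sim.t_pos[i] = t.position
            sim.t_alive[i] = True
            sim.t_phase[i] = _PHASE_TO_CODE[t.phase]
            stored = t.stored_phase if t.stored_phase is not None else Phase.G1S
            sim.t_stored[i] = _PHASE_TO_CODE[stored]
            sim.t_tleft[i] = t.phase_time_remaining
            sim.t_g2m[i] = t.g2m_duration
            sim.t_surv[i] = t.survival_remaining
        sim.n_t = n_t
        for j, c in enumerate(world.ctls):
            sim.c_pos[j] = c.position
            sim.c_mode[j] = _MODE_TO_CODE[c.mode]
            if c.bonded_target_id is not None:
                sim.c_bond[j] = tid_to_slot[c.bonded_target_id]
                sim.c_bond_t[j] = world.clock
            sim.c_kill_frac[j] = c.kill_count
            sim.c_kill_int[j] = round(c.kill_count)
        sim.n_c = n_c
        keys = []
        for bond in world.bonds:
            a, b = bond.agent_a_id, bond.agent_b_id
            if a in tid_to_slot and b in tid_to_slot:
                i, j = sorted((tid_to_slot[a], tid_to_slot[b]))
                keys.append(i * _KEY + j)
        sim.tt_keys = np.unique(np.asarray(keys, dtype=np.int64))
        return sim

    t_ids: List[str]
    c_ids: List[str]

    def _spawn_targets_steady_state(self, n: int) -> None:
        """Seed ``n`` targets with steady-state-distributed cycle ages.

        Sampling initial ages from the exponential-growth age density keeps
        a seeded culture on the N0 * 2^(t/Tc) growth curve from t = 0
        instead of dividing in synchronised bursts.
        """
        while len(self.t_alive) < n + 8:
            self._grow_targets()
        cyc = self.p.cycle
        g1s = truncated_normal(cyc.g1s_mean, cyc.g1s_sd, n, self.rng)
        g2m = truncated_normal(cyc.g2m_mean, cyc.g2m_sd, n, self.rng)
        total = g1s + g2m
        u = self.rng.random(n)
        age = -total * np.log2(1.0 - u / 2.0)
        in_g1s = age < g1s
        self.t_phase[:n] = np.where(in_g1s, _G1S, _G2M)
        self.t_tleft[:n] = np.where(in_g1s, g1s - age, total - age)
        self.t_g2m[:n] = g2m
        self.t_surv[:n] = self.p.killing.survival_duration_total
        self.t_alive[:n] = True
        self.n_t = n
        self.t_ids = [f"t{i}" for i in range(n)]

    def _append_ctls(self, positions: np.ndarray) -> None:
        n = len(positions)
        if self.n_c + n > len(self.c_mode):
            self._grow_ctls(n)
        sl = slice(self.n_c, self.n_c + n)
        self.c_pos[sl] = positions
        self.c_mode[sl] = _SEARCH
        self.c_bond[sl] = -1
        if not hasattr(self, "c_ids"):
            self.c_ids = []
        self.c_ids.extend(f"c{j}" for j in range(self.n_c, self.n_c + n))
        self.n_c += n

    def _centrifuge_positions(self, cross_section_sum: float, n: int) -> np.ndarray:
        """Uniform positions in the central disc of area 1.3x total cross-section."""
        disc_r = max(math.sqrt(1.3 * cross_section_sum), 2.0 * self.m.min_radius)
        max_r = max(self.m.target_radius, self.m.ctl_radius)
        if disc_r + max_r >= self.m.well_radius:
            raise ConfigurationError(
                f"cells do not fit: centrifugation disc radius {disc_r:.1f} um "
                f"exceeds well radius {self.m.well_radius:.1f} um"
            )
        r = disc_r * np.sqrt(self.rng.random(n))
        theta = self.rng.uniform(0.0, 2.0 * math.pi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    def _relax_world(self, max_iter: int = 200) -> None:
        tslots = np.nonzero(self.t_alive[: self.n_t])[0]
        nta = len(tslots)
        if nta + self.n_c < 2:
            return
        pos = np.vstack([self.t_pos[tslots], self.c_pos[: self.n_c]])
        rad = np.concatenate(
            [
                np.full(nta, self.m.target_radius),
                np.full(self.n_c, self.m.ctl_radius),
            ]
        )
        mech.relax_overlaps(
            pos, rad, self.m.well_radius, self.m.contact_tolerance, max_iter=max_iter
        )
        self.t_pos[tslots] = pos[:nta]
        self.c_pos[: self.n_c] = pos[nta:]

    # -- per-step phases ----------------------------------------------------

    def _detect_and_bond(self):
        tslots = np.nonzero(self.t_alive[: self.n_t])[0]
        nta = len(tslots)
        n_all = nta + self.n_c
        if n_all == 0:
            return tslots, np.zeros((0, 2), dtype=np.intp), np.zeros(0)
        pos = np.vstack([self.t_pos[tslots], self.c_pos[: self.n_c]])
        rad = np.concatenate(
            [np.full(nta, self.m.target_radius), np.full(self.n_c, self.m.ctl_radius)]
        )
        pairs, dist = mech.contact_pairs_array(pos, rad, self.m.contact_tolerance)
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            at, bt = a < nta, b < nta
            # target-target adhesion
            tt = at & bt
            if tt.any():
                sa = tslots[a[tt]]
                sb = tslots[b[tt]]
                lo = np.minimum(sa, sb)
                hi = np.maximum(sa, sb)
                keys = lo * _KEY + hi
                # sorted-array membership: cheaper than np.isin per step
                idx = np.searchsorted(self.tt_keys, keys)
                idx[idx == len(self.tt_keys)] = max(len(self.tt_keys) - 1, 0)
                if len(self.tt_keys):
                    present = self.tt_keys[idx] == keys
                else:
                    present = np.zeros(len(keys), dtype=bool)
                new = np.unique(keys[~present])
                if len(new):
                    self.tt_keys = np.sort(np.concatenate([self.tt_keys, new]))
                    stamp = self.clock + self.p.dt
                    for key in new:
                        self.events.append(
                            Event(
                                EventKind.BOND,
                                stamp,
                                self.t_ids[int(key // _KEY)],
                                self.t_ids[int(key % _KEY)],
                            )
                        )
            # CTL-target attack bonds (nearest contacting target per searching CTL)
            ct = at ^ bt
            if ct.any():
                tpacked = np.where(at[ct], a[ct], b[ct])
                cpacked = np.where(at[ct], b[ct], a[ct])
                cslot = cpacked - nta
                searching = self.c_mode[cslot] == _SEARCH
                if searching.any():
                    cslot_s = cslot[searching]
                    tslot_s = tslots[tpacked[searching]]
                    d_s = dist[ct][searching]
                    order = np.argsort(d_s, kind="stable")
                    chosen_c, first = np.unique(cslot_s[order], return_index=True)
                    chosen_t = tslot_s[order][first]
                    self.c_mode[chosen_c] = _ATTACK
                    self.c_bond[chosen_c] = chosen_t
                    self.c_bond_t[chosen_c] = self.clock
                    stamp = self.clock + self.p.dt
                    for cs, ts in zip(chosen_c, chosen_t):
                        self.events.append(
                            Event(EventKind.BOND, stamp, self.c_ids[cs], self.t_ids[ts])
                        )
        return tslots, pairs, dist

    def _kill_target(self, slot: int) -> None:
        stamp = self.clock + self.p.dt
        attackers = np.nonzero(
            (self.c_bond[: self.n_c] == slot) & (self.c_mode[: self.n_c] == _ATTACK)
        )[0]
        k = len(attackers)
        if k:
            self.c_kill_frac[attackers] += 1.0 / k
            # integer credit goes to the longest-attached attacker
            order = np.lexsort((attackers, self.c_bond_t[attackers]))
            self.c_kill_int[attackers[order[0]]] += 1.0
            self.c_mode[attackers] = _SEARCH
            self.c_bond[attackers] = -1
        self.t_alive[slot] = False
        if len(self.tt_keys):
            keep = (self.tt_keys // _KEY != slot) & (self.tt_keys % _KEY != slot)
            self.tt_keys = self.tt_keys[keep]
        self.cum_deaths += 1
        self.events.append(Event(EventKind.DEATH, stamp, self.t_ids[slot]))

    def _divide_target(self, slot: int) -> None:
        stamp = self.clock + self.p.dt
        cyc = self.p.cycle
        g1s = float(truncated_normal(cyc.g1s_mean, cyc.g1s_sd, 1, self.rng)[0])
        g2m = float(truncated_normal(cyc.g2m_mean, cyc.g2m_sd, 1, self.rng)[0])
        self.t_phase[slot] = _G1S
        self.t_tleft[slot] = g1s
        self.t_g2m[slot] = g2m
        theta = self.rng.uniform(0.0, 2.0 * math.pi)
        offset = 2.0 * self.m.target_radius * np.array([math.cos(theta), math.sin(theta)])
        if self.n_t + 1 > len(self.t_alive):
            self._grow_targets()
        d = self.n_t
        dg1s = float(truncated_normal(cyc.g1s_mean, cyc.g1s_sd, 1, self.rng)[0])
        dg2m = float(truncated_normal(cyc.g2m_mean, cyc.g2m_sd, 1, self.rng)[0])
        self.t_pos[d] = self.t_pos[slot] + offset
        lim = self.m.well_radius - self.m.target_radius
        norm = math.hypot(*self.t_pos[d])
        if norm > lim:
            self.t_pos[d] *= lim / norm
        self.t_alive[d] = True
        self.t_phase[d] = _G1S
        self.t_tleft[d] = dg1s
        self.t_g2m[d] = dg2m
        self.t_surv[d] = self.p.killing.survival_duration_total
        self.n_t += 1
        self.t_ids.append(f"t{d}")
        self.cum_divisions += 1
        self.events.append(Event(EventKind.DIVISION, stamp, self.t_ids[slot], self.t_ids[d]))

    def _update_targets(self) -> None:
        dt = self.p.dt
        n_t, n_c = self.n_t, self.n_c
        att = np.zeros(n_t, dtype=np.int64)
        bonded = self.c_bond[:n_c][self.c_mode[:n_c] == _ATTACK]
        if len(bonded):
            att += np.bincount(bonded, minlength=n_t)
        alive = self.t_alive[:n_t]
        defend = alive & (att > 0)
        entering = defend & (self.t_phase[:n_t] != _DEFENSE)
        if entering.any():
            self.t_stored[:n_t][entering] = self.t_phase[:n_t][entering]
            self.t_phase[:n_t][entering] = _DEFENSE
        if defend.any():
            self.t_surv[:n_t][defend] -= att[defend] * dt
            dead = defend & (self.t_surv[:n_t] <= 1e-9)
            for slot in np.nonzero(dead)[0]:
                self._kill_target(int(slot))
            alive = self.t_alive[:n_t]
        revert = alive & (self.t_phase[:n_t] == _DEFENSE) & (att == 0)
        if revert.any():
            self.t_phase[:n_t][revert] = self.t_stored[:n_t][revert]
            if self.p.survival_reset_on_escape:
                self.t_surv[:n_t][revert] = self.p.killing.survival_duration_total
        cycling = alive & (self.t_phase[:n_t] != _DEFENSE) & ~defend & ~revert
        if cycling.any():
            self.t_tleft[:n_t][cycling] -= dt
            to_g2m = cycling & (self.t_phase[:n_t] == _G1S) & (self.t_tleft[:n_t] <= 0)
            if to_g2m.any():
                self.t_phase[:n_t][to_g2m] = _G2M
                self.t_tleft[:n_t][to_g2m] += self.t_g2m[:n_t][to_g2m]
            dividing = cycling & (self.t_phase[:n_t] == _G2M) & (self.t_tleft[:n_t] <= 0)
            for slot in np.nonzero(dividing)[0]:
                self._divide_target(int(slot))

    def _update_ctls(self) -> None:
        p_step = self.p.killing.step_probability(self.p.dt)
        if p_step <= 0 or self.n_c == 0:
            return
        rd = self.p.killing.disabling_radius
        def_slots = np.nonzero(
            self.t_alive[: self.n_t] & (self.t_phase[: self.n_t] == _DEFENSE)
        )[0]
        if len(def_slots) == 0:
            return
        cand = np.nonzero(self.c_mode[: self.n_c] != _DISABLED)[0]
        if len(cand) == 0:
            return
        tree = cKDTree(self.t_pos[def_slots])
        if self.p.disabling_draw == "per_target":
            counts = tree.query_ball_point(
                self.c_pos[cand], rd + 1e-12, return_length=True
            )
            in_range = counts > 0
            probs = 1.0 - (1.0 - p_step) ** counts[in_range]
        else:
            dist, _ = tree.query(self.c_pos[cand], k=1, distance_upper_bound=rd + 1e-9)
            in_range = np.isfinite(dist)
            probs = p_step
        exposed = cand[in_range]
        if len(exposed) == 0:
            return
        hit = self.rng.random(len(exposed)) < probs
        stamp = self.clock + self.p.dt
        for slot in exposed[hit]:
            if self.c_bond[slot] >= 0:
                self.events.append(
                    Event(
                        EventKind.UNBOND,
                        stamp,
                        self.c_ids[slot],
                        self.t_ids[self.c_bond[slot]],
                    )
                )
            self.c_mode[slot] = _DISABLED
            self.c_bond[slot] = -1
            self.events.append(Event(EventKind.DISABLE, stamp, self.c_ids[slot]))

    def _add_cohort(self, n: int) -> None:
        if n <= 0:
            raise ParameterError(f"cohort size must be > 0, got {n}")
        alive_cells = int(self.t_alive[: self.n_t].sum()) + self.n_c + n
        max_r = max(self.m.target_radius, self.m.ctl_radius)
        if alive_cells * max_r**2 * 1.3 > 0.8 * self.m.well_radius**2:
            raise ConfigurationError(
                f"adding {n} CTL would overflow the well capacity"
            )
        positions = self._centrifuge_positions(n * self.m.ctl_radius**2, n)
        self._append_ctls(positions)
        self._relax_world(max_iter=60)

    def _step_mechanics(self, tslots, pairs, dist) -> None:
        nta = len(tslots)
        n_all = nta + self.n_c
        if n_all == 0:
            return
        pos = np.vstack([self.t_pos[tslots], self.c_pos[: self.n_c]])
        rad = np.concatenate(
            [np.full(nta, self.m.target_radius), np.full(self.n_c, self.m.ctl_radius)]
        )
        inv = np.full(self.n_t, -1, dtype=np.int64)
        inv[tslots] = np.arange(nta)
        # springs: target-target adhesion bonds
        bond_pairs = []
        rest = []
        if len(self.tt_keys):
            ia = (self.tt_keys // _KEY).astype(np.int64)
            ib = (self.tt_keys % _KEY).astype(np.int64)
            ok = (inv[ia] >= 0) & (inv[ib] >= 0)
            bp = np.column_stack([inv[ia[ok]], inv[ib[ok]]])
            bond_pairs.append(bp)
            rest.append(np.full(len(bp), 2.0 * self.m.target_radius))
        # springs: CTL attack bonds
        attack = np.nonzero(
            (self.c_mode[: self.n_c] == _ATTACK) & (self.c_bond[: self.n_c] >= 0)
        )[0]
        if len(attack):
            tgt = inv[self.c_bond[attack]]
            ok = tgt >= 0
            bp = np.column_stack([attack[ok] + nta, tgt[ok]])
            bond_pairs.append(bp)
            rest.append(np.full(len(bp), self.m.target_radius + self.m.ctl_radius))
        if bond_pairs:
            bond_pairs = np.concatenate(bond_pairs)
            rest = np.concatenate(rest)
        else:
            bond_pairs = np.zeros((0, 2), dtype=np.intp)
            rest = np.zeros(0)
        # repulsion acts on truly overlapping pairs (dead targets excluded)
        if len(pairs):
            overlap = dist < rad[pairs[:, 0]] + rad[pairs[:, 1]]
            alive_packed = np.concatenate(
                [self.t_alive[tslots], np.ones(self.n_c, dtype=bool)]
            )
            overlap &= alive_packed[pairs[:, 0]] & alive_packed[pairs[:, 1]]
            overlap_pairs = pairs[overlap]
        else:
            overlap_pairs = np.zeros((0, 2), dtype=np.intp)
        forces = mech.accumulate_forces(
            pos,
            rad,
            bond_pairs,
            rest,
            overlap_pairs,
            self.m.spring_stiffness,
            self.m.repulsion_stiffness,
        )
        pos = pos + forces / self.m.damping_coefficient * self.m.dt
        if self.m.diffusion_coefficient > 0 and self.n_c:
            moving = np.nonzero(self.c_mode[: self.n_c] != _ATTACK)[0]
            if len(moving):
                sigma = math.sqrt(2.0 * self.m.diffusion_coefficient * self.m.dt)
                pos[nta + moving] += self.rng.normal(0.0, sigma, (len(moving), 2))
        mech.clamp_to_well(pos, rad, self.m.well_radius)
        if not np.isfinite(pos).all():
            bad = int(np.nonzero(~np.isfinite(pos).all(axis=1))[0][0])
            name = self.t_ids[tslots[bad]] if bad < nta else self.c_ids[bad - nta]
            raise mech.NumericalInstabilityError(
                f"non-finite position for agent {name} at t={self.clock:.2f} min"
            )
        self.t_pos[tslots] = pos[:nta]
        self.c_pos[: self.n_c] = pos[nta:]

    def step(self) -> None:
        tslots, pairs, dist = self._detect_and_bond()
        self._update_targets()
        self._update_ctls()
        while (
            self._sched_idx < len(self._schedule)
            and self._schedule[self._sched_idx][0] <= self.clock + 1e-9
        ):
            self._add_cohort(self._schedule[self._sched_idx][1])
            self._sched_idx += 1
        self._step_mechanics(tslots, pairs, dist)
        self.clock += self.p.dt

    # -- snapshots ----------------------------------------------------------

    def counts(self) -> Dict[str, int]:
        modes = self.c_mode[: self.n_c]
        return {
            "live_targets": int(self.t_alive[: self.n_t].sum()),
            "ctl_search": int((modes == _SEARCH).sum()),
            "ctl_attack": int((modes == _ATTACK).sum()),
            "ctl_disabled": int((modes == _DISABLED).sum()),
            "ctl_total": self.n_c,
        }

    def _mass(self, slot: int) -> float:
        phase = self.t_phase[slot]
        if phase == _DEFENSE:
            phase = self.t_stored[slot]
        if phase == _G1S:
            return 1.0
        frac = 1.0 - max(self.t_tleft[slot], 0.0) / self.t_g2m[slot]
        return 1.0 + min(max(frac, 0.0), 1.0)

    def to_world(self) -> WellState:
        attackers: Dict[int, set] = {}
        for j in range(self.n_c):
            if self.c_mode[j] == _ATTACK and self.c_bond[j] >= 0:
                attackers.setdefault(int(self.c_bond[j]), set()).add(self.c_ids[j])
        targets = []
        for i in range(self.n_t):
            if not self.t_alive[i]:
                continue
            phase = _CODE_TO_PHASE[int(self.t_phase[i])]
            stored = (
                _CODE_TO_PHASE[int(self.t_stored[i])] if phase is Phase.DEFENSE else None
            )
            targets.append(
                TargetCellState(
                    id=self.t_ids[i],
                    position=self.t_pos[i].copy(),
                    radius=self.m.target_radius,
                    line=self.p.line,
                    phase=phase,
                    phase_time_remaining=float(self.t_tleft[i]),
                    g2m_duration=float(self.t_g2m[i]),
                    survival_remaining=float(self.t_surv[i]),
                    survival_total=self.p.killing.survival_duration_total,
                    mass=self._mass(i),
                    stored_phase=stored,
                    attacker_ids=attackers.get(i, set()),
                )
            )
        ctls = []
        for j in range(self.n_c):
            mode = _CODE_TO_MODE[int(self.c_mode[j])]
            kill = (
                self.c_kill_int[j]
                if self.p.kill_credit == "integer"
                else self.c_kill_frac[j]
            )
            ctls.append(
                CtlState(
                    id=self.c_ids[j],
                    position=self.c_pos[j].copy(),
                    radius=self.m.ctl_radius,
                    mode=mode,
                    kill_count=float(kill),
                    bonded_target_id=(
                        self.t_ids[self.c_bond[j]] if self.c_bond[j] >= 0 else None
                    ),
                )
            )
        bonds = []
        rest_tt = 2.0 * self.m.target_radius
        for key in self.tt_keys:
            bonds.append(
                AdhesionBond(
                    self.t_ids[int(key // _KEY)], self.t_ids[int(key % _KEY)], rest_tt
                )
            )
        rest_ct = self.m.target_radius + self.m.ctl_radius
        for j in range(self.n_c):
            if self.c_bond[j] >= 0:
                bonds.append(
                    AdhesionBond(self.c_ids[j], self.t_ids[self.c_bond[j]], rest_ct)
                )
        return WellState(clock=self.clock, targets=targets, ctls=ctls, bonds=bonds)


def initialize_well(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> WellState:
    """Build the centrifuged initial world (central aggregation, relaxed)."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    return _Sim.fresh(params, rng).to_world()


def add_ctl_cohort(
    world: WellState,
    n: int,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> WellState:
    """Add ``n`` fresh SEARCH-mode CTL by the centrifugation placement rule."""
    if n <= 0:
        raise ParameterError(f"cohort size must be > 0, got {n}")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    sim = _Sim.from_world(world, params, rng)
    sim._add_cohort(n)
    return sim.to_world()


def run_simulation(
    params: SimulationParams,
    seed: Optional[object] = None,
    initial_world: Optional[WellState] = None,
) -> RunResult:
    """Run one full co-culture simulation and return its statistics.

    ``seed`` overrides ``params.rng_seed``; it may be an int or a numpy
    ``SeedSequence``.  ``initial_world`` bypasses the centrifuged
    initialisation (used for scripted oracle scenarios).
    """
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    if initial_world is None:
        sim = _Sim.fresh(params, rng)
    else:
        sim = _Sim.from_world(initial_world, params, rng)
    rows: List[Tuple] = []

    def record() -> None:
        c = sim.counts()
        n_ctl = c["ctl_total"]
        per_capita = sim.cum_deaths / n_ctl if n_ctl else math.nan
        expected = params.initial_targets + sim.cum_divisions - sim.cum_deaths
        if initial_world is None and c["live_targets"] != expected:
            raise RuntimeError(
                f"conservation violated at t={sim.clock}: live={c['live_targets']} "
                f"!= initial {params.initial_targets} + divisions {sim.cum_divisions} "
                f"- deaths {sim.cum_deaths}"
            )
        rows.append(
            (
                sim.clock,
                c["live_targets"],
                sim.cum_deaths,
                sim.cum_divisions,
                c["ctl_search"],
                c["ctl_attack"],
                c["ctl_disabled"],
                n_ctl,
                per_capita,
            )
        )

    record()
    n_steps = math.ceil(params.duration / params.dt - 1e-9)
    rec_every = max(1, round(params.recording_interval / params.dt))
    for i in range(n_steps):
        sim.step()
        if (i + 1) % rec_every == 0 or i == n_steps - 1:
            record()
        if sim.counts()["live_targets"] > params.population_cap:
            sim.escaped = True
            break
    cols = list(zip(*rows))
    kill_frac = sim.c_kill_frac[: sim.n_c].copy()
    if abs(kill_frac.sum() - sim.cum_deaths) > 1e-6:
        raise RuntimeError(
            f"kill ledger out of balance: sum {kill_frac.sum()} != deaths {sim.cum_deaths}"
        )
    return RunResult(
        times=np.asarray(cols[0]),
        live_targets=np.asarray(cols[1]),
        cum_deaths=np.asarray(cols[2]),
        cum_divisions=np.asarray(cols[3]),
        ctl_search=np.asarray(cols[4]),
        ctl_attack=np.asarray(cols[5]),
        ctl_disabled=np.asarray(cols[6]),
        ctl_total=np.asarray(cols[7]),
        per_capita=np.asarray(cols[8], dtype=float),
        ctl_ids=list(sim.c_ids),
        kill_frac=kill_frac,
        kill_int=sim.c_kill_int[: sim.n_c].copy(),
        events=sim.events,
        seed=params.rng_seed if seed is None else seed,
        params_digest=params.digest(),
        initial_targets=params.initial_targets,
        escaped=sim.escaped,
        final_world=sim.to_world(),
    )
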