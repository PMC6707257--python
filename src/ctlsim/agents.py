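"""Agent state machines: target cells and CTL.

Target cells cycle through G1/S and G2/M, enter a defense state while under
attack, deplete a survival budget proportionally to the number of attackers
and die when it reaches zero.  CTL search by random motion, adhere to and
attack targets, and may be permanently disabled while near a defending
target.  The functions here operate on single agent records and are the
reference semantics for the vectorised engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .params import CyclePhaseParams, KillingParams, ParameterError

__all__ = [
    "Phase",
    "Mode",
    "EventKind",
    "Event",
    "StateError",
    "TargetCellState",
    "CtlState",
    "AdhesionBond",
    "draw_phase_durations",
    "truncated_normal",
    "update_target",
    "update_ctl",
    "divide_target",
]


class StateError(RuntimeError):
    """An operation was applied to an agent in an incompatible state."""


class Phase(str, Enum):
    G1S = "G1S"
    G2M = "G2M"
    DEFENSE = "DEFENSE"
    DEAD = "DEAD"


class Mode(str, Enum):
    SEARCH = "SEARCH"
    ATTACK = "ATTACK"
    DISABLED = "DISABLED"


class EventKind(str, Enum):
    DEATH = "DEATH"
    DIVISION = "DIVISION"
    DISABLE = "DISABLE"
    BOND = "BOND"
    UNBOND = "UNBOND"


@dataclass(frozen=True)
class Event:
    kind: EventKind
    time: float
    agent_id: str
    other_id: Optional[str] = None


@dataclass
class TargetCellState:
    id: str
    position: np.ndarray
    radius: float
    line: str
    phase: Phase
    phase_time_remaining: float
    g2m_duration: float
    survival_remaining: float
    survival_total: float
    mass: float = 1.0
    stored_phase: Optional[Phase] = None
    attacker_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.survival_remaining < 0 or self.survival_remaining > self.survival_total:
            raise StateError(
                f"survival_remaining {self.survival_remaining} outside [0, {self.survival_total}]"
            )


@dataclass
class CtlState:
    id: str
    position: np.ndarray
    radius: float
    mode: Mode = Mode.SEARCH
    kill_count: float = 0.0
    bonded_target_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if (self.mode is Mode.ATTACK) != (self.bonded_target_id is not None):
            raise StateError("bonded_target_id must be set iff mode is ATTACK")


@dataclass(frozen=True)
class AdhesionBond:
    agent_a_id: str
    agent_b_id: str
    rest_length: float

    def __post_init__(self) -> None:
        if self.agent_a_id == self.agent_b_id:
            raise StateError("a bond cannot connect an agent to itself")
        if self.agent_a_id.startswith("c") and self.agent_b_id.startswith("c"):
            raise StateError("CTL do not adhere to each other")

    @property
    def key(self) -> Tuple[str, str]:
        return tuple(sorted((self.agent_a_id, self.agent_b_id)))


_MAX_RESAMPLE = 100


def truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draws truncated to be strictly positive by resampling.

    After ``_MAX_RESAMPLE`` rounds any residual non-positive draws are
    clamped to 1% of the mean (degenerate parameterisations only).
    """
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(_MAX_RESAMPLE):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    out[out <= 0] = 0.01 * mean
    return out


def draw_phase_durations(
    cycle_params: CyclePhaseParams, rng: np.random.Generator
) -> Tuple[float, float]:
    """Draw (G1/S, G2/M) durations from their truncated normal laws."""
    g1s = float(truncated_normal(cycle_params.g1s_mean, cycle_params.g1s_sd, 1, rng)[0])
    g2m = float(truncated_normal(cycle_params.g2m_mean, cycle_params.g2m_sd, 1, rng)[0])
    return g1s, g2m


def update_target(
    cell: TargetCellState,
    contacting_ctl: Sequence[CtlState],
    killing: KillingParams,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    time: float = 0.0,
) -> Tuple[TargetCellState, List[Event]]:
    """Advance one target cell by one step.

    With at least one active attacker the cell is in DEFENSE: its cycle
    timer freezes and ``survival_remaining`` drops by ``k * dt`` for ``k``
    attackers.  Reaching zero emits a DEATH event.  With no active
    attackers a defending cell reverts to its frozen cycle phase; a cycling
    cell advances its phase timer and emits a DIVISION event at G2/M expiry.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt!r}")
    if cell.phase is Phase.DEAD:
        raise StateError(f"update_target called on dead cell {cell.id}")
    events: List[Event] = []
    attackers = [c for c in contacting_ctl if c.mode is Mode.ATTACK]
    k = len(attackers)
    if k > 0:
        if cell.phase is not Phase.DEFENSE:
            cell.stored_phase = cell.phase
            cell.phase = Phase.DEFENSE
        cell.attacker_ids = {c.id for c in attackers}
        cell.survival_remaining = max(0.0, cell.survival_remaining - k * dt)
        if cell.survival_remaining <= 1e-12:
            cell.survival_remaining = 0.0
            cell.phase = Phase.DEAD
            events.append(Event(EventKind.DEATH, time, cell.id))
        return cell, events
    cell.attacker_ids = set()
    if cell.phase is Phase.DEFENSE:
        cell.phase = cell.stored_phase if cell.stored_phase is not None else Phase.G1S
        cell.stored_phase = None
        return cell, events
    cell.phase_time_remaining -= dt
    if cell.phase is Phase.G1S and cell.phase_time_remaining <= 0:
        cell.phase = Phase.G2M
        cell.phase_time_remaining += cell.g2m_duration
    if cell.phase is Phase.G2M:
        frac = 1.0 - max(cell.phase_time_remaining, 0.0) / cell.g2m_duration
        cell.mass = 1.0 + min(max(frac, 0.0), 1.0)
        if cell.phase_time_remaining <= 0:
            events.append(Event(EventKind.DIVISION, time, cell.id))
    return cell, events


def update_ctl(
    ctl: CtlState,
    contacting_targets: Sequence[TargetCellState],
    defending_targets_in_radius: int,
    killing: KillingParams,
    dt: float,
    rng: np.random.Generator,
    time: float = 0.0,
    disabling_draw: str = "per_ctl",
) -> Tuple[CtlState, List[Event]]:
    """Advance one CTL by one step.

    A searching CTL adheres to the first contacting live target and switches
    to ATTACK.  Any non-disabled CTL within the disabling radius of at least
    one defending target is permanently disabled with the step-rescaled
    probability (one draw per CTL by default, one per nearby defending
    target in ``per_target`` mode).  DISABLED is absorbing.
    """
    events: List[Event] = []
    if ctl.mode is Mode.DISABLED:
        return ctl, events
    if ctl.mode is Mode.SEARCH:
        for target in contacting_targets:
            if target.phase is not Phase.DEAD:
                ctl.mode = Mode.ATTACK
                ctl.bonded_target_id = target.id
                events.append(Event(EventKind.BOND, time, ctl.id, target.id))
                break
    if defending_targets_in_radius > 0:
        p = killing.step_probability(dt)
        if disabling_draw == "per_target":
            p = 1.0 - (1.0 - p) ** defending_targets_in_radius
        if p > 0 and rng.random() < p:
            if ctl.bonded_target_id is not None:
                events.append(Event(EventKind.UNBOND, time, ctl.id, ctl.bonded_target_id))
            ctl.mode = Mode.DISABLED
            ctl.bonded_target_id = None
            events.append(Event(EventKind.DISABLE, time, ctl.id))
    return ctl, events


def divide_target(
    mother: TargetCellState,
    cycle_params: CyclePhaseParams,
    rng: np.random.Generator,
    daughter_id: str,
) -> Tuple[TargetCellState, TargetCellState]:
    """Split a target at G2/M expiry into a reset mother and a daughter.

    The daughter is placed at centre distance ``2 * radius`` along a
    uniformly random direction; both cells restart G1/S with freshly drawn
    phase durations and unit mass.
    """
    if mother.phase is not Phase.G2M or mother.phase_time_remaining > 1e-9:
        raise StateError(
            f"divide_target requires a mother at G2/M expiry; got phase={mother.phase}, "
            f"time remaining={mother.phase_time_remaining}"
        )
    g1s, g2m = draw_phase_durations(cycle_params, rng)
    mother.phase = Phase.G1S
    mother.phase_time_remaining = g1s
    mother.g2m_duration = g2m
    mother.mass = 1.0
    theta = rng.uniform(0.0, 2.0 * math.pi)
    offset = 2.0 * mother.radius * np.array([math.cos(theta), math.sin(theta)])
    dg1s, dg2m = draw_phase_durations(cycle_params, rng)
    daughter = TargetCellState(
        id=daughter_id,
        position=mother.position + offset,
        radius=mother.radius,
        line=mother.line,
        phase=Phase.G1S,
        phase_time_remaining=dg1s,
        g2m_duration=dg2m,
        survival_remaining=mother.survival_total,
        survival_total=mother.survival_total,
    )
    return mother, daughter
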