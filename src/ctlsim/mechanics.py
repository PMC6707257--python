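"""Continuous 2-D cell mechanics.

Cells are inertia-free discs in a circular well.  Adhesion bonds act as
springs toward their rest length, overlapping pairs repel proportionally to
overlap, and the overdamped update converts net force into displacement
through the damping coefficient.  Searching and disabled CTL additionally
receive Brownian displacements.

The array-level helpers (`pair_distances`, `accumulate_forces`,
`relax_overlaps`) are shared between the record-based API here and the
vectorised engine.
"""

from __future__ import annotations

import copy
import math
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .agents import Mode
from .params import MechanicsParams, ParameterError

__all__ = [
    "NumericalInstabilityError",
    "brownian_displacement",
    "step_mechanics",
    "neighbors_within",
    "detect_contacts",
    "pair_distances",
    "accumulate_forces",
    "relax_overlaps",
    "clamp_to_well",
]


class NumericalInstabilityError(RuntimeError):
    """A force or position became non-finite during integration."""


def brownian_displacement(
    diffusion_coefficient: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One Brownian step: zero-mean normal with per-axis variance 2*D*dt."""
    if diffusion_coefficient < 0:
        raise ParameterError(
            f"diffusion_coefficient must be >= 0, got {diffusion_coefficient!r}"
        )
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt!r}")
    if diffusion_coefficient == 0:
        return np.zeros(2)
    sigma = math.sqrt(2.0 * diffusion_coefficient * dt)
    return rng.normal(0.0, sigma, 2)


def pair_distances(
    positions: np.ndarray, pairs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Distances and unit vectors (a -> b) for an (m, 2) index pair array."""
    if len(pairs) == 0:
        return np.zeros(0), np.zeros((0, 2))
    delta = positions[pairs[:, 1]] - positions[pairs[:, 0]]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    safe = np.where(dist > 1e-12, dist, 1.0)
    unit = delta / safe[:, None]
    return dist, unit


def accumulate_forces(
    positions: np.ndarray,
    radii: np.ndarray,
    bond_pairs: np.ndarray,
    bond_rest_lengths: np.ndarray,
    overlap_pairs: np.ndarray,
    spring_stiffness: float,
    repulsion_stiffness: float,
) -> np.ndarray:
    """Net spring + repulsion force on every agent.

    Bonded pairs feel a linear spring toward the rest length; every
    overlapping pair (bonded or not) feels a repulsion proportional to the
    overlap depth.
    """
    forces = np.zeros_like(positions)
    if len(bond_pairs):
        dist, unit = pair_distances(positions, bond_pairs)
        magnitude = spring_stiffness * (dist - bond_rest_lengths)
        f = magnitude[:, None] * unit  # pulls a toward b when stretched
        np.add.at(forces, bond_pairs[:, 0], f)
        np.add.at(forces, bond_pairs[:, 1], -f)
    if len(overlap_pairs):
        dist, unit = pair_distances(positions, overlap_pairs)
        overlap = radii[overlap_pairs[:, 0]] + radii[overlap_pairs[:, 1]] - dist
        overlap = np.maximum(overlap, 0.0)
        f = (repulsion_stiffness * overlap)[:, None] * unit
        np.add.at(forces, overlap_pairs[:, 0], -f)
        np.add.at(forces, overlap_pairs[:, 1], f)
    return forces


def contact_pairs_array(
    positions: np.ndarray, radii: np.ndarray, tolerance: float
) -> Tuple[np.ndarray, np.ndarray]:
    """All pairs with centre distance <= (r_a + r_b) * (1 + tolerance)."""
    if len(positions) < 2:
        return np.zeros((0, 2), dtype=np.intp), np.zeros(0)
    cutoff = 2.0 * radii.max() * (1.0 + tolerance)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.zeros(0)
    dist, _ = pair_distances(positions, pairs)
    keep = dist <= (radii[pairs[:, 0]] + radii[pairs[:, 1]]) * (1.0 + tolerance)
    return pairs[keep], dist[keep]


def clamp_to_well(
    positions: np.ndarray, radii: np.ndarray, well_radius: float
) -> np.ndarray:
    """Radially clamp centres so every disc stays inside the well wall."""
    r = np.hypot(positions[:, 0], positions[:, 1])
    limit = well_radius - radii
    outside = r > limit
    if outside.any():
        scale = limit[outside] / r[outside]
        positions[outside] *= scale[:, None]
    return positions


def relax_overlaps(
    positions: np.ndarray,
    radii: np.ndarray,
    well_radius: float,
    tolerance: float,
    max_iter: int = 300,
    push: float = 0.4,
) -> np.ndarray:
    """Iteratively separate overlapping discs (deterministic packing relax).

    Each round moves both members of every overlapping pair apart by
    ``push`` times the overlap, then clamps to the well; stops when the
    worst relative overlap drops below ``tolerance``.
    """
    for _ in range(max_iter):
        pairs, dist = contact_pairs_array(positions, radii, 0.0)
        if len(pairs) == 0:
            break
        rsum = radii[pairs[:, 0]] + radii[pairs[:, 1]]
        overlap = rsum - dist
        active = overlap > tolerance * rsum
        if not active.any():
            break
        pairs = pairs[active]
        overlap = overlap[active]
        _, unit = pair_distances(positions, pairs)
        shift = (push * overlap)[:, None] * unit
        np.add.at(positions, pairs[:, 0], -shift)
        np.add.at(positions, pairs[:, 1], shift)
        clamp_to_well(positions, radii, well_radius)
    return positions


# ---------------------------------------------------------------------------
# Record-level API on WellState
# ---------------------------------------------------------------------------


def _world_arrays(world):
    ids = [t.id for t in world.targets] + [c.id for c in world.ctls]
    if not ids:
        return ids, np.zeros((0, 2)), np.zeros(0)
    positions = np.array(
        [t.position for t in world.targets] + [c.position for c in world.ctls],
        dtype=float,
    )
    radii = np.array(
        [t.radius for t in world.targets] + [c.radius for c in world.ctls], dtype=float
    )
    return ids, positions, radii


def neighbors_within(world, position, radius: float) -> Set[str]:
    """Ids of all agents within ``radius`` of ``position`` (inclusive)."""
    if radius < 0:
        raise ParameterError(f"radius must be >= 0, got {radius!r}")
    ids, positions, _ = _world_arrays(world)
    if not ids:
        return set()
    position = np.asarray(position, dtype=float)
    dist = np.hypot(*(positions - position).T)
    return {ids[i] for i in np.nonzero(dist <= radius + 1e-12)[0]}


def detect_contacts(world, tolerance: float = 0.05) -> List[Tuple[str, str]]:
    """Touching pairs: centre distance <= (r_a + r_b) * (1 + tolerance)."""
    ids, positions, radii = _world_arrays(world)
    pairs, _ = contact_pairs_array(positions, radii, tolerance)
    out = []
    for a, b in pairs:
        key = tuple(sorted((ids[a], ids[b])))
        out.append(key)
    return sorted(out)


def step_mechanics(world, params: MechanicsParams, rng=None):
    """Advance all positions by one overdamped step; returns a new world.

    Brownian displacements apply only to CTL in SEARCH or DISABLED mode and
    only when ``rng`` is given.  Raises
    :class:`NumericalInstabilityError` naming the first offending agent if
    any position becomes non-finite.
    """
    new_world = copy.deepcopy(world)
    ids, positions, radii = _world_arrays(new_world)
    n = len(ids)
    if n == 0:
        return new_world
    index = {agent_id: i for i, agent_id in enumerate(ids)}
    bond_pairs = []
    rest = []
    for bond in new_world.bonds:
        if bond.agent_a_id in index and bond.agent_b_id in index:
            bond_pairs.append((index[bond.agent_a_id], index[bond.agent_b_id]))
            rest.append(bond.rest_length)
    bond_pairs = np.asarray(bond_pairs, dtype=np.intp).reshape(-1, 2)
    rest = np.asarray(rest, dtype=float)
    overlap_pairs, _ = contact_pairs_array(positions, radii, 0.0)
    forces = accumulate_forces(
        positions,
        radii,
        bond_pairs,
        rest,
        overlap_pairs,
        params.spring_stiffness,
        params.repulsion_stiffness,
    )
    if not np.isfinite(forces).all():
        bad = int(np.nonzero(~np.isfinite(forces).all(axis=1))[0][0])
        raise NumericalInstabilityError(f"non-finite force on agent {ids[bad]}")
    positions = positions + forces / params.damping_coefficient * params.dt
    if rng is not None and params.diffusion_coefficient > 0:
        n_targets = len(new_world.targets)
        for j, ctl in enumerate(new_world.ctls):
            if ctl.mode in (Mode.SEARCH, Mode.DISABLED):
                positions[n_targets + j] += brownian_displacement(
                    params.diffusion_coefficient, params.dt, rng
                )
    clamp_to_well(positions, radii, params.well_radius)
    if not np.isfinite(positions).all():
        bad = int(np.nonzero(~np.isfinite(positions).all(axis=1))[0][0])
        raise NumericalInstabilityError(f"non-finite position for agent {ids[bad]}")
    for i, t in enumerate(new_world.targets):
        t.position = positions[i].copy()
    for j, c in enumerate(new_world.ctls):
        c.position = positions[len(new_world.targets) + j].copy()
    return new_world
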