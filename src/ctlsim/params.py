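"""Parameter records for the co-culture simulator.

All lengths are micrometres and all times are minutes internally; the
configuration layer (:mod:`ctlsim.config`) converts from hours at the
user interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "CONVENTIONAL",
    "MELANOMA",
    "LINES",
    "MechanicsParams",
    "CyclePhaseParams",
    "KillingParams",
    "SimulationParams",
    "default_cycle_params",
    "default_killing_params",
    "default_simulation_params",
]


class ParameterError(ValueError):
    """A parameter violates its domain constraints."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


CONVENTIONAL = "conventional"
MELANOMA = "melanoma"
LINES = (CONVENTIONAL, MELANOMA)


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ParameterError(f"{name} must be strictly positive, got {value!r}")


def _require_nonneg(name: str, value: float) -> None:
    if not (value >= 0):
        raise ParameterError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class MechanicsParams:
    """Constants of the continuous 2-D physical world.

    The integration scheme is overdamped: forces translate into velocities
    through ``damping_coefficient`` and positions advance by one ``dt`` per
    step.  Construction verifies that a single step's characteristic
    displacement (one Brownian standard deviation plus the elastic
    displacement of a fully overlapping pair) stays below half the smallest
    cell radius, which keeps contact detection stable.
    """

    spring_stiffness: float = 0.1  # force per um of bond extension
    damping_coefficient: float = 1.0  # force per (um/min) of velocity
    repulsion_stiffness: float = 0.2  # force per um of overlap
    diffusion_coefficient: float = 1.0  # um^2/min Brownian motility
    dt: float = 0.5  # min
    well_radius: float = 1500.0  # um
    target_radius: float = 8.0  # um
    ctl_radius: float = 5.0  # um
    contact_tolerance: float = 0.05  # fraction of summed radii

    def __post_init__(self) -> None:
        for name in (
            "spring_stiffness",
            "damping_coefficient",
            "repulsion_stiffness",
            "dt",
            "well_radius",
            "target_radius",
            "ctl_radius",
        ):
            _require_positive(name, getattr(self, name))
        _require_nonneg("diffusion_coefficient", self.diffusion_coefficient)
        _require_nonneg("contact_tolerance", self.contact_tolerance)
        if self.characteristic_step_displacement() >= 0.5 * self.min_radius:
            raise ParameterError(
                "dt too large for mechanical stability: one step's "
                f"characteristic displacement {self.characteristic_step_displacement():.3g} um "
                f">= 0.5 * min cell radius {0.5 * self.min_radius:.3g} um; reduce dt "
                "or the diffusion coefficient"
            )

    @property
    def min_radius(self) -> float:
        return min(self.target_radius, self.ctl_radius)

    @property
    def max_contact_distance(self) -> float:
        r = max(self.target_radius, self.ctl_radius)
        return 2.0 * r * (1.0 + self.contact_tolerance)

    def characteristic_step_displacement(self) -> float:
        brownian = math.sqrt(2.0 * self.diffusion_coefficient * self.dt)
        stiff = max(self.spring_stiffness, self.repulsion_stiffness)
        elastic = stiff / self.damping_coefficient * self.min_radius * self.dt
        return brownian + elastic

    def contact_distance(self, radius_a: float, radius_b: float) -> float:
        return (radius_a + radius_b) * (1.0 + self.contact_tolerance)


@dataclass(frozen=True)
class CyclePhaseParams:
    """Normal-law cycle-phase durations (minutes) for one target line."""

    g1s_mean: float
    g1s_sd: float
    g2m_mean: float
    g2m_sd: float

    def __post_init__(self) -> None:
        _require_positive("g1s_mean", self.g1s_mean)
        _require_positive("g2m_mean", self.g2m_mean)
        _require_nonneg("g1s_sd", self.g1s_sd)
        _require_nonneg("g2m_sd", self.g2m_sd)

    @property
    def total_mean(self) -> float:
        return self.g1s_mean + self.g2m_mean


@dataclass(frozen=True)
class KillingParams:
    """Survival-duration depletion and probabilistic CTL inactivation.

    ``disabling_probability`` is a per-step Bernoulli probability expressed
    at ``reference_dt``; :meth:`step_probability` rescales it through the
    hazard identity so behaviour is invariant to the integration step.
    """

    survival_duration_total: float  # min, time for one CTL to kill one target
    disabling_radius: float = 100.0  # um (R_d)
    disabling_probability: float = 0.001  # per reference_dt step (P_d)
    reference_dt: float = 0.5  # min

    def __post_init__(self) -> None:
        _require_positive("survival_duration_total", self.survival_duration_total)
        _require_nonneg("disabling_radius", self.disabling_radius)
        _require_positive("reference_dt", self.reference_dt)
        if not (0.0 <= self.disabling_probability <= 1.0):
            raise ParameterError(
                f"disabling_probability must lie in [0, 1], got {self.disabling_probability!r}"
            )

    def step_probability(self, dt: float) -> float:
        """Disabling probability for one step of length ``dt`` minutes."""
        if dt <= 0:
            raise ParameterError(f"dt must be positive, got {dt!r}")
        if dt == self.reference_dt or self.disabling_probability in (0.0, 1.0):
            return self.disabling_probability
        return 1.0 - (1.0 - self.disabling_probability) ** (dt / self.reference_dt)


# Repo-default calibrated constants per target line.  The survival
# durations and the (R_d, P_d) couple below were obtained by calibrating
# 18 h in-silico killing assays against published population-scale
# cytotoxicity measurements; they are configuration, not ground truth.
_CYCLE_DEFAULTS = {
    CONVENTIONAL: CyclePhaseParams(
        g1s_mean=990.0, g1s_sd=99.0, g2m_mean=330.0, g2m_sd=33.0
    ),
    MELANOMA: CyclePhaseParams(
        g1s_mean=1170.0, g1s_sd=117.0, g2m_mean=390.0, g2m_sd=39.0
    ),
}

_SURVIVAL_DEFAULTS = {CONVENTIONAL: 47.0, MELANOMA: 220.0}

DEFAULT_DISABLING_RADIUS = 100.0
DEFAULT_DISABLING_PROBABILITY = 0.0003
DEFAULT_REFERENCE_DT = 1.0


def default_cycle_params(line: str) -> CyclePhaseParams:
    try:
        return _CYCLE_DEFAULTS[line]
    except KeyError:
        raise ParameterError(f"unknown cell line {line!r}; expected one of {LINES}")


def default_killing_params(line: str) -> KillingParams:
    try:
        survival = _SURVIVAL_DEFAULTS[line]
    except KeyError:
        raise ParameterError(f"unknown cell line {line!r}; expected one of {LINES}")
    return KillingParams(
        survival_duration_total=survival,
        disabling_radius=DEFAULT_DISABLING_RADIUS,
        disabling_probability=DEFAULT_DISABLING_PROBABILITY,
        reference_dt=DEFAULT_REFERENCE_DT,
    )


@dataclass(frozen=True)
class SimulationParams:
    """Everything needed to run one co-culture simulation."""

    line: str = MELANOMA
    dt: float = 1.0  # min
    duration: float = 1080.0  # min (18 h)
    initial_targets: int = 1000
    initial_ctl: Optional[int] = None
    et_ratio: Optional[float] = None
    killing: KillingParams = field(default_factory=lambda: default_killing_params(MELANOMA))
    cycle: CyclePhaseParams = field(default_factory=lambda: default_cycle_params(MELANOMA))
    mechanics: MechanicsParams = field(default_factory=lambda: MechanicsParams(dt=1.0))
    cohort_schedule: Tuple[Tuple[float, int], ...] = ()  # (time_min, ctl_count)
    rng_seed: int = 0
    recording_interval: float = 15.0  # min
    kill_credit: str = "fractional"  # ledger reflected by CtlState.kill_count
    disabling_draw: str = "per_ctl"  # or "per_target"
    survival_reset_on_escape: bool = False
    population_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.line not in LINES:
            raise ParameterError(f"unknown cell line {self.line!r}; expected one of {LINES}")
        _require_positive("dt", self.dt)
        _require_nonneg("duration", self.duration)
        if self.initial_targets < 0:
            raise ParameterError("initial_targets must be >= 0")
        if self.initial_ctl is not None and self.initial_ctl < 0:
            raise ParameterError("initial_ctl must be >= 0")
        if self.et_ratio is not None and self.et_ratio < 0:
            raise ParameterError("et_ratio must be >= 0")
        if self.initial_ctl is None and self.et_ratio is None:
            object.__setattr__(self, "initial_ctl", 0)
        if self.kill_credit not in ("fractional", "integer"):
            raise ParameterError("kill_credit must be 'fractional' or 'integer'")
        if self.disabling_draw not in ("per_ctl", "per_target"):
            raise ParameterError("disabling_draw must be 'per_ctl' or 'per_target'")
        _require_positive("recording_interval", self.recording_interval)
        if self.population_cap <= 0:
            raise ParameterError("population_cap must be positive")
        schedule = tuple((float(t), int(n)) for t, n in self.cohort_schedule)
        object.__setattr__(self, "cohort_schedule", schedule)
        last = -math.inf
        for t, n in schedule:
            if not (0.0 <= t <= self.duration):
                raise ParameterError(
                    f"cohort_schedule time {t} outside [0, duration={self.duration}]"
                )
            if t < last:
                raise ParameterError("cohort_schedule times must be non-decreasing")
            if n <= 0:
                raise ParameterError(f"cohort_schedule counts must be > 0, got {n}")
            last = t
        if self.mechanics.dt != self.dt:
            object.__setattr__(
                self, "mechanics", dataclasses.replace(self.mechanics, dt=self.dt)
            )

    @property
    def n_initial_ctl(self) -> int:
        if self.initial_ctl is not None:
            return int(self.initial_ctl)
        return int(round(self.et_ratio * self.initial_targets))

    def digest(self) -> str:
        """Stable hash of all parameter values (provenance for outputs)."""
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def default_simulation_params(line: str = MELANOMA, **overrides) -> SimulationParams:
    """Repo-default calibrated parameter set for one cell line.

    The calibrated defaults use the per-defending-target disabling draw:
    its effective inactivation rate grows with local target density, which
    is what quantitatively reproduces both the sharp decline of per-capita
    killing with E/T ratio and the growth-control boundary of the ratio
    sweep.  The plain per-CTL draw remains available via
    ``disabling_draw='per_ctl'``.
    """
    base = dict(
        line=line,
        killing=default_killing_params(line),
        cycle=default_cycle_params(line),
        disabling_draw="per_target",
    )
    base.update(overrides)
    return SimulationParams(**base)
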