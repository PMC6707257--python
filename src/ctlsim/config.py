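"""Configuration files: YAML (or JSON) round-tripping of run setups.

Interface units are hours for durations and schedule times (keys suffixed
``_h``), minutes for the integration step (``dt_min`` - sub-minute steps
are the norm), and micrometres for lengths (``_um``).  Internally
everything is minutes/micrometres (see :mod:`ctlsim.params`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .params import (
    ConfigurationError,
    CyclePhaseParams,
    KillingParams,
    MechanicsParams,
    SimulationParams,
    default_cycle_params,
    default_killing_params,
    MELANOMA,
)

__all__ = ["RunConfig", "parse_config", "write_config"]

logger = logging.getLogger("ctlsim")


@dataclass
class RunConfig:
    simulation: SimulationParams
    scenario: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "info"


_TOP_KEYS = {"simulation", "scenario", "seed", "out_dir", "log_level"}
_SIM_KEYS = {
    "line",
    "dt_min",
    "duration_h",
    "initial_targets",
    "initial_ctl",
    "et_ratio",
    "recording_interval_min",
    "kill_credit",
    "disabling_draw",
    "survival_reset_on_escape",
    "population_cap",
    "cohort_schedule",
    "killing",
    "cycle",
    "mechanics",
}
_KILLING_KEYS = {
    "survival_duration_total_min",
    "disabling_radius_um",
    "disabling_probability",
    "reference_dt_min",
}
_CYCLE_KEYS = {"g1s_mean_h", "g1s_sd_h", "g2m_mean_h", "g2m_sd_h"}
_MECH_KEYS = {
    "spring_stiffness",
    "damping_coefficient",
    "repulsion_stiffness",
    "diffusion_coefficient",
    "well_radius_um",
    "target_radius_um",
    "ctl_radius_um",
    "contact_tolerance",
}
_SCENARIO_KEYS = {
    "kind",
    "et_ratios",
    "n_runs",
    "duration_h",
    "ratio_min",
    "ratio_max",
    "step",
    "schedules",
    "bolus_total",
    "noise_sd",
    "runs_per_point",
    "rd_values",
    "pd_values",
}


def _check_keys(block: Dict[str, Any], allowed: set, path: str) -> None:
    if not isinstance(block, dict):
        raise ConfigurationError(f"'{path}' must be a mapping")
    for key in block:
        if key not in allowed:
            raise ConfigurationError(f"unknown key '{path}.{key}'" if path else f"unknown key '{key}'")


def _get(block: Dict[str, Any], key: str, default: Any, path: str) -> Any:
    if key in block:
        return block[key]
    logger.debug("config: '%s.%s' absent, default %r applied", path, key, default)
    return default


def _parse_simulation(block: Dict[str, Any]) -> SimulationParams:
    _check_keys(block, _SIM_KEYS, "simulation")
    line = _get(block, "line", MELANOMA, "simulation")
    killing_defaults = default_killing_params(line)
    cycle_defaults = default_cycle_params(line)

    kb = block.get("killing", {})
    _check_keys(kb, _KILLING_KEYS, "simulation.killing")
    killing = KillingParams(
        survival_duration_total=_get(
            kb,
            "survival_duration_total_min",
            killing_defaults.survival_duration_total,
            "simulation.killing",
        ),
        disabling_radius=_get(
            kb, "disabling_radius_um", killing_defaults.disabling_radius, "simulation.killing"
        ),
        disabling_probability=_get(
            kb,
            "disabling_probability",
            killing_defaults.disabling_probability,
            "simulation.killing",
        ),
        reference_dt=_get(
            kb, "reference_dt_min", killing_defaults.reference_dt, "simulation.killing"
        ),
    )
    cb = block.get("cycle", {})
    _check_keys(cb, _CYCLE_KEYS, "simulation.cycle")
    cycle = CyclePhaseParams(
        g1s_mean=60.0 * _get(cb, "g1s_mean_h", cycle_defaults.g1s_mean / 60.0, "simulation.cycle"),
        g1s_sd=60.0 * _get(cb, "g1s_sd_h", cycle_defaults.g1s_sd / 60.0, "simulation.cycle"),
        g2m_mean=60.0 * _get(cb, "g2m_mean_h", cycle_defaults.g2m_mean / 60.0, "simulation.cycle"),
        g2m_sd=60.0 * _get(cb, "g2m_sd_h", cycle_defaults.g2m_sd / 60.0, "simulation.cycle"),
    )
    mb = block.get("mechanics", {})
    _check_keys(mb, _MECH_KEYS, "simulation.mechanics")
    dt = float(_get(block, "dt_min", 1.0, "simulation"))
    mech_defaults = MechanicsParams(dt=dt)
    mechanics = MechanicsParams(
        spring_stiffness=_get(mb, "spring_stiffness", mech_defaults.spring_stiffness, "simulation.mechanics"),
        damping_coefficient=_get(mb, "damping_coefficient", mech_defaults.damping_coefficient, "simulation.mechanics"),
        repulsion_stiffness=_get(mb, "repulsion_stiffness", mech_defaults.repulsion_stiffness, "simulation.mechanics"),
        diffusion_coefficient=_get(mb, "diffusion_coefficient", mech_defaults.diffusion_coefficient, "simulation.mechanics"),
        dt=dt,
        well_radius=_get(mb, "well_radius_um", mech_defaults.well_radius, "simulation.mechanics"),
        target_radius=_get(mb, "target_radius_um", mech_defaults.target_radius, "simulation.mechanics"),
        ctl_radius=_get(mb, "ctl_radius_um", mech_defaults.ctl_radius, "simulation.mechanics"),
        contact_tolerance=_get(mb, "contact_tolerance", mech_defaults.contact_tolerance, "simulation.mechanics"),
    )
    schedule = tuple(
        (60.0 * float(t), int(n))
        for t, n in _get(block, "cohort_schedule", [], "simulation")
    )
    duration_h = _get(block, "duration_h", 18.0, "simulation")
    if duration_h is None or float(duration_h) < 0:
        raise ConfigurationError(f"'simulation.duration_h' must be >= 0, got {duration_h!r}")
    return SimulationParams(
        line=line,
        dt=dt,
        duration=60.0 * float(duration_h),
        initial_targets=int(_get(block, "initial_targets", 1000, "simulation")),
        initial_ctl=block.get("initial_ctl"),
        et_ratio=block.get("et_ratio"),
        killing=killing,
        cycle=cycle,
        mechanics=mechanics,
        cohort_schedule=schedule,
        recording_interval=float(_get(block, "recording_interval_min", 15.0, "simulation")),
        kill_credit=_get(block, "kill_credit", "fractional", "simulation"),
        disabling_draw=_get(block, "disabling_draw", "per_ctl", "simulation"),
        survival_reset_on_escape=bool(
            _get(block, "survival_reset_on_escape", False, "simulation")
        ),
        population_cap=int(_get(block, "population_cap", 100_000, "simulation")),
    )


def parse_config(path) -> RunConfig:
    """Parse a YAML/JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
    _check_keys(raw, _TOP_KEYS, "")
    scenario = raw.get("scenario", {}) or {}
    _check_keys(scenario, _SCENARIO_KEYS, "scenario")
    try:
        simulation = _parse_simulation(raw.get("simulation", {}) or {})
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid simulation block in {path}: {exc}") from exc
    return RunConfig(
        simulation=simulation,
        scenario=dict(scenario),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "results")),
        log_level=str(raw.get("log_level", "info")),
    )


def config_to_dict(config: RunConfig) -> Dict[str, Any]:
    """Serialise a RunConfig back to the interface-unit dictionary."""
    p = config.simulation
    m = p.mechanics
    k = p.killing
    c = p.cycle
    return {
        "seed": config.seed,
        "out_dir": config.out_dir,
        "log_level": config.log_level,
        "simulation": {
            "line": p.line,
            "dt_min": p.dt,
            "duration_h": p.duration / 60.0,
            "initial_targets": p.initial_targets,
            "initial_ctl": p.initial_ctl,
            "et_ratio": p.et_ratio,
            "recording_interval_min": p.recording_interval,
            "kill_credit": p.kill_credit,
            "disabling_draw": p.disabling_draw,
            "survival_reset_on_escape": p.survival_reset_on_escape,
            "population_cap": p.population_cap,
            "cohort_schedule": [[t / 60.0, n] for t, n in p.cohort_schedule],
            "killing": {
                "survival_duration_total_min": k.survival_duration_total,
                "disabling_radius_um": k.disabling_radius,
                "disabling_probability": k.disabling_probability,
                "reference_dt_min": k.reference_dt,
            },
            "cycle": {
                "g1s_mean_h": c.g1s_mean / 60.0,
                "g1s_sd_h": c.g1s_sd / 60.0,
                "g2m_mean_h": c.g2m_mean / 60.0,
                "g2m_sd_h": c.g2m_sd / 60.0,
            },
            "mechanics": {
                "spring_stiffness": m.spring_stiffness,
                "damping_coefficient": m.damping_coefficient,
                "repulsion_stiffness": m.repulsion_stiffness,
                "diffusion_coefficient": m.diffusion_coefficient,
                "well_radius_um": m.well_radius,
                "target_radius_um": m.target_radius,
                "ctl_radius_um": m.ctl_radius,
                "contact_tolerance": m.contact_tolerance,
            },
        },
        "scenario": config.scenario,
    }


def write_config(config: RunConfig, path) -> None:
    """Write a config as YAML; ``parse_config`` round-trips it losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
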