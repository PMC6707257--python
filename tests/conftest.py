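import dataclasses

import numpy as np
import pytest

from ctlsim.agents import CtlState, Mode, Phase, TargetCellState
from ctlsim.engine import RunResult, WellState
from ctlsim.params import (
    CyclePhaseParams,
    KillingParams,
    MechanicsParams,
    SimulationParams,
    default_simulation_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small, fast calibrated-default world for integration tests."""
    return default_simulation_params(
        "melanoma", initial_targets=40, et_ratio=0.5, duration=120.0
    )


def make_pinned_params(
    survival=300.0,
    dt=0.5,
    duration=400.0,
    p_d=0.0,
    r_d=100.0,
    diffusion=0.0,
    line="melanoma",
):
    """Deterministic params: no motility, no disabling, effectively no cycling."""
    return SimulationParams(
        line=line,
        dt=dt,
        duration=duration,
        initial_targets=0,
        initial_ctl=0,
        killing=KillingParams(
            survival_duration_total=survival,
            disabling_radius=r_d,
            disabling_probability=p_d,
            reference_dt=dt,
        ),
        cycle=CyclePhaseParams(g1s_mean=1e9, g1s_sd=0.0, g2m_mean=1e9, g2m_sd=0.0),
        mechanics=MechanicsParams(dt=dt, diffusion_coefficient=diffusion),
        recording_interval=dt,
    )


def make_target(tid, position, params, phase=Phase.G1S, survival=None):
    k = params.killing
    return TargetCellState(
        id=tid,
        position=np.asarray(position, dtype=float),
        radius=params.mechanics.target_radius,
        line=params.line,
        phase=phase,
        phase_time_remaining=params.cycle.g1s_mean,
        g2m_duration=params.cycle.g2m_mean,
        survival_remaining=k.survival_duration_total if survival is None else survival,
        survival_total=k.survival_duration_total,
    )


def make_ctl(cid, position, params, mode=Mode.SEARCH, bonded=None):
    return CtlState(
        id=cid,
        position=np.asarray(position, dtype=float),
        radius=params.mechanics.ctl_radius,
        mode=mode,
        bonded_target_id=bonded,
    )


def make_pinned_world(params, target_positions, ctl_positions):
    """A scripted world: targets and CTL at exact positions, no bonds yet."""
    targets = [
        make_target(f"t{i}", pos, params) for i, pos in enumerate(target_positions)
    ]
    ctls = [make_ctl(f"c{j}", pos, params) for j, pos in enumerate(ctl_positions)]
    return WellState(clock=0.0, targets=targets, ctls=ctls, bonds=[])


def make_run_result(times, cum_deaths, ctl_total, kill_int=None, **overrides):
    """Minimal synthetic RunResult for analysis-level tests."""
    times = np.asarray(times, dtype=float)
    cum_deaths = np.asarray(cum_deaths, dtype=float)
    ctl_total = np.asarray(ctl_total, dtype=float)
    n = len(times)
    n_ctl = int(ctl_total[-1]) if len(ctl_total) else 0
    kill_int = (
        np.zeros(n_ctl) if kill_int is None else np.asarray(kill_int, dtype=float)
    )
    defaults = dict(
        times=times,
        live_targets=np.zeros(n),
        cum_deaths=cum_deaths,
        cum_divisions=np.zeros(n),
        ctl_search=ctl_total,
        ctl_attack=np.zeros(n),
        ctl_disabled=np.zeros(n),
        ctl_total=ctl_total,
        per_capita=np.where(ctl_total > 0, cum_deaths / np.maximum(ctl_total, 1), np.nan),
        ctl_ids=[f"c{i}" for i in range(len(kill_int))],
        kill_frac=kill_int.copy(),
        kill_int=kill_int,
        events=[],
        seed=0,
        params_digest="synthetic",
        initial_targets=0,
        escaped=False,
        final_world=WellState(clock=float(times[-1]) if n else 0.0, targets=[], ctls=[], bonds=[]),
    )
    defaults.update(overrides)
    return RunResult(**defaults)
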