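"""The in-silico experiment suite: killing assays across E/T ratios,
optimal-ratio sweep, long-duration runs, and sequential CTL-cohort
addition compared against a single initial bolus."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analysis import rank_sum_test
from .engine import RunResult, run_simulation
from .params import ConfigurationError, ParameterError, SimulationParams

__all__ = [
    "CALIBRATION_RATIOS",
    "AssayDesign",
    "CohortSchedule",
    "KillingCurve",
    "OptimalRatioResult",
    "SequentialComparison",
    "killing_assay",
    "optimal_ratio_search",
    "long_term_experiment",
    "sequential_addition_experiment",
    "ratio_grid",
]

#: E/T ratios available experimentally, used for calibration.
CALIBRATION_RATIOS = (0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class AssayDesign:
    et_ratios: Tuple[float, ...] = CALIBRATION_RATIOS
    duration: float = 1080.0  # min (18 h)
    n_runs: int = 20
    line: Optional[str] = None  # default: the line of the supplied params

    def __post_init__(self) -> None:
        if not self.et_ratios:
            raise ParameterError("et_ratios must not be empty")
        if any(r < 0 for r in self.et_ratios):
            raise ParameterError("et_ratios must be >= 0")
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        object.__setattr__(self, "et_ratios", tuple(sorted(self.et_ratios)))


@dataclass(frozen=True)
class CohortSchedule:
    """CTL additions as (time_min, count); time-0 entries form the seed bolus."""

    additions: Tuple[Tuple[float, int], ...]

    def __post_init__(self) -> None:
        additions = tuple((float(t), int(n)) for t, n in self.additions)
        if not additions:
            raise ParameterError("schedule must contain at least one addition")
        times = [t for t, _ in additions]
        if any(t < 0 for t in times) or sorted(times) != times:
            raise ParameterError("schedule times must be non-negative and non-decreasing")
        if any(n <= 0 for _, n in additions):
            raise ParameterError("schedule counts must be > 0")
        object.__setattr__(self, "additions", additions)

    @property
    def total_ctl(self) -> int:
        return sum(n for _, n in self.additions)

    @property
    def initial_ctl(self) -> int:
        return sum(n for t, n in self.additions if t == 0.0)

    @property
    def deferred(self) -> Tuple[Tuple[float, int], ...]:
        return tuple((t, n) for t, n in self.additions if t > 0.0)


@dataclass
class KillingCurve:
    """Cytotoxicity vs E/T ratio table (simulated or reference).

    ``data`` columns: line, et_ratio, cytotoxicity (percent of initial
    targets killed), cytotoxicity_sd, per_capita, per_capita_sd, n_runs.
    """

    data: pd.DataFrame
    measure_kind: str = "percent_killed"

    def __post_init__(self) -> None:
        required = {"line", "et_ratio", "cytotoxicity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ConfigurationError(f"KillingCurve missing columns: {sorted(missing)}")
        self.data = self.data.sort_values(["line", "et_ratio"]).reset_index(drop=True)

    def cells(self) -> pd.DataFrame:
        return self.data[["line", "et_ratio", "cytotoxicity"]]


def _run_seeds(master_seed: int, *indices: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])


def _assay_runs(
    params: SimulationParams,
    ratio: float,
    n_runs: int,
    duration: float,
    seed: int,
    tag: int,
    common_random_numbers: bool = False,
) -> List[RunResult]:
    p = dataclasses.replace(
        params, et_ratio=float(ratio), initial_ctl=None, duration=float(duration)
    )
    if common_random_numbers:
        # same seed stream for every ratio: noise shifts the whole curve
        # coherently instead of independently per grid point
        seeds = [_run_seeds(seed, tag, i) for i in range(n_runs)]
    else:
        seeds = [
            _run_seeds(seed, tag, int(round(ratio * 1e6)), i) for i in range(n_runs)
        ]
    return [run_simulation(p, seed=s) for s in seeds]


def killing_assay(
    design: AssayDesign, params: SimulationParams, seed: int = 0
) -> Tuple[KillingCurve, pd.DataFrame]:
    """Run the killing assay over the design's ratio grid.

    Returns the aggregated :class:`KillingCurve` (mean +/- sd of percent of
    initial targets killed and of per-capita kills across ``n_runs``) plus
    the per-run tidy table.
    """
    line = design.line or params.line
    if line != params.line:
        from .params import default_cycle_params, default_killing_params

        params = dataclasses.replace(
            params,
            line=line,
            killing=default_killing_params(line),
            cycle=default_cycle_params(line),
        )
    run_rows = []
    agg_rows = []
    for ri, ratio in enumerate(design.et_ratios):
        results = _assay_runs(params, ratio, design.n_runs, design.duration, seed, ri)
        pct = np.array(
            [100.0 * r.total_deaths / r.initial_targets for r in results]
        )
        n_ctl = results[0].ctl_total[-1]
        if n_ctl > 0:
            k = np.array([r.total_deaths / r.ctl_total[-1] for r in results])
            k_mean, k_sd = float(k.mean()), float(k.std(ddof=1)) if len(k) > 1 else 0.0
        else:
            k_mean = k_sd = math.nan
        for i, r in enumerate(results):
            run_rows.append(
                {
                    "line": line,
                    "et_ratio": ratio,
                    "run": i,
                    "pct_killed": 100.0 * r.total_deaths / r.initial_targets,
                    "per_capita": r.total_deaths / n_ctl if n_ctl else math.nan,
                    "final_targets": r.final_live_targets,
                }
            )
        agg_rows.append(
            {
                "line": line,
                "et_ratio": ratio,
                "cytotoxicity": float(pct.mean()),
                "cytotoxicity_sd": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
                "per_capita": k_mean,
                "per_capita_sd": k_sd,
                "n_runs": design.n_runs,
            }
        )
    curve = KillingCurve(pd.DataFrame(agg_rows))
    return curve, pd.DataFrame(run_rows)


def ratio_grid(ratio_min: float, ratio_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic ratio grid, robust to float step accumulation."""
    if not ratio_min < ratio_max:
        raise ParameterError("ratio_min must be < ratio_max")
    if step <= 0:
        raise ParameterError("step must be > 0")
    n = int(math.floor((ratio_max - ratio_min) / step + 1e-9)) + 1
    return np.round(ratio_min + step * np.arange(n), 10)


@dataclass
class OptimalRatioResult:
    optimal_ratio: Optional[float]  # None when no grid ratio controls growth
    mean_final_targets: float
    sd_final_targets: float
    controlled: bool
    table: pd.DataFrame  # per-ratio mean/sd of final live targets


def optimal_ratio_search(
    params: SimulationParams,
    ratio_min: float = 0.5,
    ratio_max: float = 1.0,
    step: float = 0.005,
    duration: float = 1080.0,
    n_runs: int = 20,
    seed: int = 0,
) -> OptimalRatioResult:
    """Sweep the ratio grid; return the smallest ratio controlling growth.

    "Controlling growth" means the mean final live-target count over
    ``n_runs`` does not exceed the initial target count (net growth <= 0
    over the assay window, without CTL excess).  All grid points share the
    same random-number streams (common random numbers): independent noise
    per point would bias the first crossing of a shallow mean curve toward
    smaller ratios.
    """
    grid = ratio_grid(ratio_min, ratio_max, step)
    rows = []
    for ri, ratio in enumerate(grid):
        results = _assay_runs(
            params, ratio, n_runs, duration, seed, 10_000, common_random_numbers=True
        )
        finals = np.array([r.final_live_targets for r in results], dtype=float)
        rows.append(
            {
                "et_ratio": float(ratio),
                "mean_final_targets": float(finals.mean()),
                "sd_final_targets": float(finals.std(ddof=1)) if n_runs > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    controlled = table[table.mean_final_targets <= params.initial_targets]
    if len(controlled):
        best = controlled.iloc[0]
        return OptimalRatioResult(
            optimal_ratio=float(best.et_ratio),
            mean_final_targets=float(best.mean_final_targets),
            sd_final_targets=float(best.sd_final_targets),
            controlled=True,
            table=table,
        )
    return OptimalRatioResult(
        optimal_ratio=None,
        mean_final_targets=math.nan,
        sd_final_targets=math.nan,
        controlled=False,
        table=table,
    )


def long_term_experiment(
    params: SimulationParams,
    et_ratios: Sequence[float],
    duration: float = 21600.0,  # min (360 h)
    n_runs: int = 20,
    seed: int = 0,
    max_duration: float = 21600.0,
) -> Dict[float, pd.DataFrame]:
    """Mean +/- sd live-target trajectories per ratio over a long window.

    Runs whose population exceeds the configured hard cap are truncated by
    the engine and flagged ``escaped``; their trajectories contribute up to
    the truncation point.
    """
    if duration > max_duration:
        raise ParameterError(
            f"duration {duration} exceeds the configured maximum {max_duration}"
        )
    out: Dict[float, pd.DataFrame] = {}
    for ri, ratio in enumerate(sorted(et_ratios)):
        results = _assay_runs(params, ratio, n_runs, duration, seed, 20_000 + ri)
        n_rows = min(len(r.times) for r in results)
        live = np.vstack([r.live_targets[:n_rows] for r in results]).astype(float)
        out[float(ratio)] = pd.DataFrame(
            {
                "time_h": results[0].times[:n_rows] / 60.0,
                "mean_live_targets": live.mean(axis=0),
                "sd_live_targets": live.std(axis=0, ddof=1) if n_runs > 1 else 0.0,
                "escaped": any(r.escaped for r in results),
            }
        )
    return out


@dataclass
class SequentialComparison:
    per_run: pd.DataFrame  # arm, run, final_targets
    comparison: pd.DataFrame  # arm vs bolus rank-sum statistics


def sequential_addition_experiment(
    params: SimulationParams,
    schedules: Sequence[CohortSchedule],
    bolus_total: int,
    n_runs: int = 20,
    duration: Optional[float] = None,
    seed: int = 0,
) -> SequentialComparison:
    """Compare sequential CTL cohorts against a single initial bolus.

    Every schedule must add exactly ``bolus_total`` CTL in total (the
    comparison is only meaningful at equal effector numbers).  Returns the
    per-run final live-target counts per arm and two-sided rank-sum
    p-values of each sequential arm against the bolus arm.
    """
    for s in schedules:
        if s.total_ctl != bolus_total:
            raise ConfigurationError(
                f"schedule total {s.total_ctl} != bolus total {bolus_total}; "
                "arms must match in CTL numbers"
            )
    duration = params.duration if duration is None else float(duration)

    def arm_runs(initial_ctl: int, deferred, tag: int) -> np.ndarray:
        p = dataclasses.replace(
            params,
            initial_ctl=initial_ctl,
            et_ratio=None,
            cohort_schedule=deferred,
            duration=duration,
        )
        finals = [
            run_simulation(p, seed=_run_seeds(seed, 30_000 + tag, i)).final_live_targets
            for i in range(n_runs)
        ]
        return np.asarray(finals, dtype=float)

    rows = []
    bolus_finals = arm_runs(bolus_total, (), 0)
    for i, v in enumerate(bolus_finals):
        rows.append({"arm": "bolus", "run": i, "final_targets": v})
    comparison = []
    for si, schedule in enumerate(schedules):
        finals = arm_runs(schedule.initial_ctl, schedule.deferred, si + 1)
        arm = f"schedule_{si}"
        for i, v in enumerate(finals):
            rows.append({"arm": arm, "run": i, "final_targets": v})
        stat, p = rank_sum_test(finals, bolus_finals)
        comparison.append(
            {
                "arm": arm,
                "schedule": schedule.additions,
                "mean_final_targets": float(finals.mean()),
                "bolus_mean_final_targets": float(bolus_finals.mean()),
                "rank_sum_statistic": stat,
                "p_value": p,
            }
        )
    return SequentialComparison(
        per_run=pd.DataFrame(rows), comparison=pd.DataFrame(comparison)
    )
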