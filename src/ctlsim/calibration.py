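"""Calibration: cell-cycle fitting from growth counts and exhaustive
(R_d, P_d) grid search against reference killing curves."""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import (
    ConfigurationError,
    CyclePhaseParams,
    KillingParams,
    ParameterError,
    SimulationParams,
)
from .scenarios import AssayDesign, CALIBRATION_RATIOS, KillingCurve, killing_assay

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "CalibrationGrid",
    "fit_growth",
    "mse_distance",
    "grid_search_rd_pd",
    "default_rd_values",
    "default_pd_values",
]


def default_rd_values() -> np.ndarray:
    """Disabling-radius grid: 50 to 400 um in 12.5 um steps (29 values)."""
    return np.round(np.arange(50.0, 400.0 + 1e-9, 12.5), 6)


def default_pd_values() -> np.ndarray:
    """Disabling-probability grid: 0.00025 to 0.01 in 0.00025 steps (40 values)."""
    return np.round(np.arange(0.00025, 0.01 + 1e-12, 0.00025), 10)


@dataclass(frozen=True)
class GrowthSeries:
    """Live-cell counts over time for one target line in free growth."""

    observations: Tuple[Tuple[float, float], ...]  # (time_min, count)
    line: str
    initial_count: float

    def __post_init__(self) -> None:
        obs = tuple((float(t), float(c)) for t, c in self.observations)
        times = [t for t, _ in obs]
        if sorted(set(times)) != times:
            raise ParameterError("observation times must be strictly increasing")
        if any(c <= 0 for _, c in obs):
            raise ParameterError("counts must be strictly positive")
        object.__setattr__(self, "observations", obs)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations])

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.observations])


@dataclass(frozen=True)
class GrowthFit:
    cycle: CyclePhaseParams
    doubling_time: float  # min; inf sentinel for flat/declining series
    r_squared: float
    flat: bool


def fit_growth(
    series: GrowthSeries,
    phase_split: float = 0.75,
    sd_fraction: float = 0.1,
) -> GrowthFit:
    """Fit the mean total cycle duration from exponential growth counts.

    The doubling time comes from a log2-linear regression of count on
    time; the mean total cycle duration equals the doubling time and is
    split into G1/S and G2/M means by ``phase_split``, with standard
    deviations set to ``sd_fraction`` of each mean.
    """
    if len(series.observations) < 3:
        raise ParameterError("fit_growth needs at least 3 observations")
    t = series.times
    y = np.log2(series.counts)
    if np.any(np.diff(series.counts) < 0):
        warnings.warn("growth series is not monotone increasing; fitting anyway")
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope <= 1e-12:
        cycle = CyclePhaseParams(
            g1s_mean=1.0, g1s_sd=0.0, g2m_mean=1.0, g2m_sd=0.0
        )
        return GrowthFit(cycle=cycle, doubling_time=math.inf, r_squared=r2, flat=True)
    doubling = 1.0 / slope
    g1s = phase_split * doubling
    g2m = (1.0 - phase_split) * doubling
    cycle = CyclePhaseParams(
        g1s_mean=g1s,
        g1s_sd=sd_fraction * g1s,
        g2m_mean=g2m,
        g2m_sd=sd_fraction * g2m,
    )
    return GrowthFit(cycle=cycle, doubling_time=doubling, r_squared=r2, flat=False)


def mse_distance(simulated: KillingCurve, reference: KillingCurve) -> float:
    """Mean squared cytotoxicity difference over shared (line, ratio) cells."""
    sim = simulated.cells().set_index(["line", "et_ratio"])
    ref = reference.cells().set_index(["line", "et_ratio"])
    if sorted(sim.index) != sorted(ref.index):
        raise ConfigurationError(
            "killing curves are not aligned: "
            f"simulated cells {sorted(sim.index)} vs reference {sorted(ref.index)}"
        )
    diff = sim.cytotoxicity - ref.cytotoxicity
    return float((diff**2).mean())


@dataclass
class CalibrationGrid:
    """Scored (R_d, P_d) grid with the best couple.

    Ties are broken toward smaller P_d, then smaller R_d.
    """

    rd_values: np.ndarray = field(default_factory=default_rd_values)
    pd_values: np.ndarray = field(default_factory=default_pd_values)
    runs_per_point: int = 10
    scores: Optional[pd.DataFrame] = None  # columns rd, pd, score
    best: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.rd_values = np.asarray(self.rd_values, dtype=float)
        self.pd_values = np.asarray(self.pd_values, dtype=float)
        if len(self.rd_values) == 0 or len(self.pd_values) == 0:
            raise ParameterError("calibration grid axes must be non-empty")
        if self.runs_per_point < 1:
            raise ParameterError("runs_per_point must be >= 1")

    @property
    def size(self) -> int:
        return len(self.rd_values) * len(self.pd_values)


def grid_search_rd_pd(
    grid: CalibrationGrid,
    reference: KillingCurve,
    params_by_line: Dict[str, SimulationParams],
    et_ratios: Optional[Sequence[float]] = None,
    duration: float = 1080.0,
    seed: int = 0,
) -> CalibrationGrid:
    """Exhaustively score every (R_d, P_d) couple against the reference.

    For each grid point, killing assays are simulated for every reference
    line over the reference ratio grid (``runs_per_point`` runs each) and
    scored by :func:`mse_distance`; the argmin is recorded in
    ``grid.best``.
    """
    ref_lines = sorted(reference.data.line.unique())
    missing = set(ref_lines) - set(params_by_line)
    if missing:
        raise ConfigurationError(f"no simulation params for reference lines {sorted(missing)}")
    if et_ratios is None:
        et_ratios = sorted(reference.data.et_ratio.unique())
    ref_subset = KillingCurve(
        reference.data[reference.data.et_ratio.isin(et_ratios)].copy(),
        measure_kind=reference.measure_kind,
    )
    rows = []
    best = None
    best_score = math.inf
    for rd in grid.rd_values:
        for pd_ in grid.pd_values:
            frames = []
            for line in ref_lines:
                p = params_by_line[line]
                p = dataclasses.replace(
                    p,
                    killing=dataclasses.replace(
                        p.killing,
                        disabling_radius=float(rd),
                        disabling_probability=float(pd_),
                    ),
                )
                design = AssayDesign(
                    et_ratios=tuple(et_ratios),
                    duration=duration,
                    n_runs=grid.runs_per_point,
                    line=line,
                )
                curve, _ = killing_assay(design, p, seed=seed)
                frames.append(curve.data)
            sim_curve = KillingCurve(pd.concat(frames, ignore_index=True))
            score = mse_distance(sim_curve, ref_subset)
            rows.append({"rd": float(rd), "pd": float(pd_), "score": score})
            # strict improvement keeps the smallest (pd, rd) on ties because
            # of ascending traversal order
            if score < best_score - 1e-15:
                best_score = score
                best = (float(rd), float(pd_))
    scores = pd.DataFrame(rows)
    if not np.isfinite(scores.score).all():
        raise RuntimeError("calibration produced non-finite scores")
    # enforce documented tie-break regardless of traversal order
    tol = 1e-12
    minimal = scores[scores.score <= scores.score.min() + tol]
    minimal = minimal.sort_values(["pd", "rd"]).iloc[0]
    grid.scores = scores
    grid.best = (float(minimal.rd), float(minimal.pd))
    return grid
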