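"""Synthetic reference data: killing curves and growth series.

Stands in for experimental calibration inputs so the calibration pipeline
(parameter recovery in particular) is testable without external data.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import GrowthSeries
from .engine import run_simulation
from .params import ParameterError, SimulationParams
from .scenarios import AssayDesign, CALIBRATION_RATIOS, KillingCurve

__all__ = ["ReferenceFixture", "generate_reference_fixture", "write_fixture", "read_reference_curve"]


@dataclass
class ReferenceFixture:
    killing_curves: KillingCurve
    growth_series: Dict[str, GrowthSeries]
    truth: Dict[str, Dict[str, float]]  # per line: R_d, P_d, S, Tc used
    seed: int
    noise_sd: float


def generate_reference_fixture(
    true_params: Dict[str, SimulationParams],
    noise_sd: float = 0.0,
    seed: int = 0,
    et_ratios: Sequence[float] = CALIBRATION_RATIOS,
    n_runs: int = 3,
    assay_duration: float = 1080.0,
    growth_duration: float = 4320.0,
    growth_sampling: float = 1440.0,
) -> ReferenceFixture:
    """Simulate reference killing curves and growth counts at known truth.

    Independent Gaussian noise of sd ``noise_sd`` (percentage points) is
    added to the cytotoxicity values; the generating parameters are
    recorded for later recovery checks.
    """
    from .scenarios import killing_assay

    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd!r}")
    rng = np.random.default_rng(seed)
    frames = []
    growth: Dict[str, GrowthSeries] = {}
    truth: Dict[str, Dict[str, float]] = {}
    for line in sorted(true_params):
        p = true_params[line]
        design = AssayDesign(
            et_ratios=tuple(et_ratios), duration=assay_duration, n_runs=n_runs, line=line
        )
        curve, _ = killing_assay(design, p, seed=seed)
        data = curve.data.copy()
        if noise_sd > 0:
            data["cytotoxicity"] = data["cytotoxicity"] + rng.normal(
                0.0, noise_sd, len(data)
            )
        frames.append(data)
        gp = dataclasses.replace(
            p,
            initial_ctl=0,
            et_ratio=None,
            duration=growth_duration,
            recording_interval=growth_sampling,
        )
        line_tag = zlib.crc32(line.encode())
        res = run_simulation(gp, seed=np.random.SeedSequence([seed, line_tag]))
        obs = tuple(
            (float(t), float(n)) for t, n in zip(res.times, res.live_targets) if n > 0
        )
        growth[line] = GrowthSeries(
            observations=obs, line=line, initial_count=p.initial_targets
        )
        truth[line] = {
            "disabling_radius": p.killing.disabling_radius,
            "disabling_probability": p.killing.disabling_probability,
            "survival_duration_total": p.killing.survival_duration_total,
            "total_cycle_mean": p.cycle.total_mean,
        }
    return ReferenceFixture(
        killing_curves=KillingCurve(pd.concat(frames, ignore_index=True)),
        growth_series=growth,
        truth=truth,
        seed=seed,
        noise_sd=noise_sd,
    )


def write_fixture(fixture: ReferenceFixture, out_dir) -> Dict[str, Path]:
    """Write fixture CSVs in the calibration input dialect plus a truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = fixture.killing_curves.data.copy()
    curves["measure_kind"] = fixture.killing_curves.measure_kind
    curves_path = out_dir / "reference_killing_curves.csv"
    curves.to_csv(curves_path, index=False, float_format="%.10g")
    rows = []
    for line, series in sorted(fixture.growth_series.items()):
        for t, n in series.observations:
            rows.append({"line": line, "time_h": t / 60.0, "count": n})
    growth_path = out_dir / "reference_growth_series.csv"
    pd.DataFrame(rows).to_csv(growth_path, index=False, float_format="%.10g")
    truth_path = out_dir / "fixture_truth.json"
    truth_path.write_text(
        json.dumps(
            {"seed": fixture.seed, "noise_sd": fixture.noise_sd, "truth": fixture.truth},
            indent=2,
            sort_keys=True,
        )
    )
    return {"curves": curves_path, "growth": growth_path, "truth": truth_path}


def read_reference_curve(path, default_basal_fraction: Optional[float] = None) -> KillingCurve:
    """Read a reference killing-curve CSV.

    Expected columns: line, et_ratio, cytotoxicity, optional measure_kind
    in {percent_killed, fold_over_basal} and optional basal_fraction.
    Fold-increase measurements are converted to percent of targets killed
    over basal using the per-row basal death fraction.
    """
    df = pd.read_csv(path, comment="#")
    required = {"line", "et_ratio", "cytotoxicity"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"reference curve missing columns {sorted(missing)}")
    if "measure_kind" not in df.columns:
        df["measure_kind"] = "percent_killed"
    fold = df.measure_kind == "fold_over_basal"
    if fold.any():
        if "basal_fraction" not in df.columns:
            if default_basal_fraction is None:
                import warnings

                warnings.warn(
                    "fold_over_basal rows without basal_fraction; assuming 0.05"
                )
                default_basal_fraction = 0.05
            df["basal_fraction"] = default_basal_fraction
        df.loc[fold, "cytotoxicity"] = (
            (df.loc[fold, "cytotoxicity"] - 1.0).clip(lower=0.0)
            * df.loc[fold, "basal_fraction"]
            * 100.0
        )
        df["measure_kind"] = "percent_killed"
    return KillingCurve(df[["line", "et_ratio", "cytotoxicity"]].copy())
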