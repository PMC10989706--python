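"""Pipeline orchestration: read data, fit, select, and write report files.

These functions add no computation of their own; every number written to
disk is reproducible by calling the library operations with the
configuration echoed into ``report.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vanthoff.data_model import VantHoffSeries, read_series
from vanthoff.fitting import FitConfig, ModelSelectionReport, select_model
from vanthoff.synthetic import TwoStateModelSpec, simulate_lnkeq_series, simulate_open_prob
from vanthoff.thermo import compute_thermo, q10_curve

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_fit", "run_simulate", "run_q10"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str | Path
    output_dir: str | Path
    temperature_unit: str = "K"
    fit: FitConfig = field(default_factory=FitConfig)
    p_min: float = 0.01
    p_max: float = 0.99
    grid_points: int = 200
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid resolution must be at least 2 points")


def _load(config: RunConfig) -> VantHoffSeries:
    series = read_series(
        config.input_path,
        temperature_unit=config.temperature_unit,
        p_bounds=(config.p_min, config.p_max),
    )
    assert isinstance(series, VantHoffSeries)
    return series


def _temperature_grid(report: ModelSelectionReport, n: int) -> np.ndarray:
    fit = report.selected
    x_lo, x_hi = fit.x_data[0], fit.x_data[-1]
    if fit.scale == "reciprocal":
        T_lo, T_hi = 1.0 / x_hi, 1.0 / x_lo
    else:
        T_lo, T_hi = x_lo, x_hi
    return np.linspace(T_lo, T_hi, n)


def run_fit(config: RunConfig) -> ModelSelectionReport:
    """Fit an input table and write report.json + curves.csv (+ plots)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = _load(config)
    if len(series) < 3:
        raise ValueError(
            f"only {len(series)} usable data points; at least 3 are needed for a fit"
        )
    report = select_model(series, config.fit, sigma_supplied=series.sigma_supplied)
    report.to_json(out / "report.json")
    curves = compute_thermo(report.selected, _temperature_grid(report, config.grid_points))
    curves.to_csv(out / "curves.csv")
    if config.make_plots:
        from vanthoff.plots import plot_fit_panels

        plot_fit_panels(series, report, curves, out)
    logger.info(
        "selected %s scale with N=%d (BIC=%.3f); wrote %s",
        report.selected.scale, report.selected.n_intervals, report.selected.bic, out,
    )
    return report


def run_q10(config: RunConfig) -> ModelSelectionReport:
    """Fit as in :func:`run_fit` and additionally write q10.csv."""
    report = run_fit(config)
    grid = _temperature_grid(report, config.grid_points)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grid points with T+10 out of range are dropped
        q10 = q10_curve(report.selected, grid)
    q10.to_csv(Path(config.output_dir) / "q10.csv")
    return report


def run_simulate(
    spec: TwoStateModelSpec,
    T_grid,
    output_dir: str | Path,
    seed: int = 0,
    mode: str = "lnkeq",
) -> Path:
    """Write a simulated dataset plus a sidecar JSON with the ground truth."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mode == "lnkeq":
        series = simulate_lnkeq_series(spec, T_grid, seed=seed)
        data_path = out / "simulated_lnkeq.csv"
        series.to_frame().to_csv(data_path, index=False)
    elif mode == "open_prob":
        table = simulate_open_prob(spec, T_grid, seed=seed)
        data_path = out / "simulated_open_prob.csv"
        table.to_frame().to_csv(data_path, index=False)
    else:
        raise ValueError("mode must be 'lnkeq' or 'open_prob'")
    sidecar = {
        "T0": spec.T0,
        "dH0_J_per_mol": spec.dH0,
        "dS0_J_per_mol_K": spec.dS0,
        "dCp_J_per_mol_K": spec.dCp if not callable(spec.dCp) else "callable",
        "sigma_y": spec.sigma_y,
        "sigma_P": spec.sigma_P,
        "n_replicates": spec.n_replicates,
        "seed": seed,
        "mode": mode,
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return data_path
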