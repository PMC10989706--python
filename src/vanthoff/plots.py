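"""Diagnostic figures for a fitted van 't Hoff model."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vanthoff.constants import GAS_CONSTANT
from vanthoff.data_model import VantHoffSeries
from vanthoff.fitting import ModelSelectionReport
from vanthoff.thermo import ThermoCurves

__all__ = ["plot_fit_panels"]


def plot_fit_panels(
    series: VantHoffSeries,
    report: ModelSelectionReport,
    curves: ThermoCurves,
    output_dir: str | Path,
) -> list[Path]:
    """Write the standard four panels: fit, dG, dH & TdS, dCp.

    Temperature intervals where the spline is no longer constrained by
    data points are shaded; the curve shape there should not be trusted.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit = report.selected
    T = curves.temperature_K
    paths = []

    def shade(ax):
        unconstrained = ~curves.constrained
        if unconstrained.any():
            ax.fill_between(
                T, 0, 1, where=unconstrained, transform=ax.get_xaxis_transform(),
                color="0.85", zorder=0,
            )

    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = 1.0 / series.temperature_K if fit.scale == "reciprocal" else series.temperature_K
    xg = 1.0 / T if fit.scale == "reciprocal" else T
    spline = fit.spline()
    ax.errorbar(x, series.lnkeq, yerr=series.sigma, fmt="o", ms=4, label="data")
    order = np.argsort(xg)
    ax.plot(xg[order], np.asarray(spline(xg))[order], "-",
            label=f"{fit.scale}, N={fit.n_intervals}")
    ax.set_xlabel("1/T (1/K)" if fit.scale == "reciprocal" else "T (K)")
    ax.set_ylabel(r"$\ln K_\mathrm{eq}$")
    ax.legend(frameon=False)
    p = out / "fit.png"
    fig.tight_layout(); fig.savefig(p, dpi=150); plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    shade(ax)
    ax.plot(T, curves.dG / 1e3, "-", color="C0")
    ax.plot(series.temperature_K, -GAS_CONSTANT * series.temperature_K * series.lnkeq / 1e3,
            "o", ms=4, color="C0")
    ax.set_xlabel("T (K)"); ax.set_ylabel(r"$\Delta G$ (kJ/mol)")
    p = out / "dG.png"
    fig.tight_layout(); fig.savefig(p, dpi=150); plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    shade(ax)
    ax.plot(T, curves.dH / 1e3, "-", color="C0", label=r"$\Delta H$")
    ax.plot(T, curves.TdS / 1e3, "--", color="C3", label=r"$T\Delta S$")
    ax.set_xlabel("T (K)"); ax.set_ylabel("kJ/mol")
    ax.legend(frameon=False)
    p = out / "dH_TdS.png"
    fig.tight_layout(); fig.savefig(p, dpi=150); plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    shade(ax)
    ax.plot(T, curves.dCp / 1e3, "-", color="C0")
    ax.set_xlabel("T (K)"); ax.set_ylabel(r"$\Delta C_p$ (kJ/(mol K))")
    p = out / "dCp.png"
    fig.tight_layout(); fig.savefig(p, dpi=150); plt.close(fig)
    paths.append(p)

    return paths
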