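"""Thermodynamic curves derived from a fitted van 't Hoff spline.

With S(x) the fitted spline for ln(Keq) in the fit coordinate x(T), the
two-state potentials follow analytically:

    dG(T) = -R T S(x(T))
    dH(T) =  R T^2 (dx/dT) S'(x(T))
    dS(T) = (dH - dG) / T
    dCp(T) = d(dH)/dT
           = R d/dT[T^2 dx/dT] S'(x) + R T^2 (dx/dT)^2 S''(x)

On the reciprocal scale x = 1/T the prefactor T^2 dx/dT = -1 is constant,
so the first dCp term vanishes and dCp = R S''(x) / T^2; on the linear
scale dCp = 2 R T S'(T) + R T^2 S''(T).  Writing the first term with the
derivative acting only on the prefactor makes dCp identically the
temperature derivative of dH, consistent with Cp = (dH/dT) at constant
pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from vanthoff.constants import GAS_CONSTANT
from vanthoff.fitting import FitResult

__all__ = ["ThermoCurves", "Q10Curve", "compute_thermo", "q10_curve", "dh_from_qdelta"]


@dataclass(frozen=True)
class ThermoCurves:
    """dG, dH, dS and dCp between the open and closed states on a T grid.

    Energies are in J/mol and entropies/heat capacities in J/(mol K).
    ``constrained[i]`` is False where the grid point sits farther (in the
    fit coordinate) from every data point than the mean inter-datum
    spacing; the spline shape is not trusted there.
    """

    temperature_K: np.ndarray
    dG: np.ndarray
    dH: np.ndarray
    dS: np.ndarray
    dCp: np.ndarray
    constrained: np.ndarray
    scale: str
    gas_constant: float = GAS_CONSTANT

    @property
    def TdS(self) -> np.ndarray:
        return self.temperature_K * self.dS

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable table in SI units plus kJ display columns."""
        return pd.DataFrame(
            {
                "T_K": self.temperature_K,
                "dG_J_per_mol": self.dG,
                "dH_J_per_mol": self.dH,
                "TdS_J_per_mol": self.TdS,
                "dS_J_per_mol_K": self.dS,
                "dCp_J_per_mol_K": self.dCp,
                "constrained": self.constrained,
                "dG_kJ_per_mol": self.dG / 1e3,
                "dH_kJ_per_mol": self.dH / 1e3,
                "TdS_kJ_per_mol": self.TdS / 1e3,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class Q10Curve:
    """Q10 temperature coefficient and the enthalpy it implies."""

    temperature_K: np.ndarray
    q10: np.ndarray
    dH_q10: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T_K": self.temperature_K, "Q10": self.q10, "dH_Q10_J_per_mol": self.dH_q10}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _x_of_T(T: np.ndarray, scale: str) -> np.ndarray:
    if scale == "linear":
        return T
    if scale == "reciprocal":
        return 1.0 / T
    raise ValueError(f"unknown scale {scale!r}")


def compute_thermo(
    fit: FitResult,
    T_grid: np.ndarray,
    constrained_spacing_factor: float = 1.0,
) -> ThermoCurves:
    """Evaluate the thermodynamic potentials of a fit on a temperature grid.

    Parameters
    ----------
    fit
        A converged free-knot fit; its spline domain limits the admissible
        grid (no extrapolation).
    T_grid
        Absolute temperatures in Kelvin, each mapping into the spline
        domain under the fit's scale.
    constrained_spacing_factor
        A grid point is flagged as data-constrained when some data point
        lies within this multiple of the mean inter-datum spacing in x.
    """
    T = np.asarray(T_grid, dtype=float)
    if np.any(T <= 0):
        raise ValueError("grid temperatures must be positive")
    R = GAS_CONSTANT
    spline = fit.spline()
    x = _x_of_T(T, fit.scale)

    S0 = np.asarray(spline(x))
    S1 = np.asarray(spline(x, order=1))
    S2 = np.asarray(spline(x, order=2))

    dG = -R * T * S0
    if fit.scale == "reciprocal":
        # T^2 dx/dT = -1: dH = -R S', dCp = R S'' / T^2
        dH = -R * S1
        dCp = R * S2 / T**2
    else:
        dH = R * T**2 * S1
        dCp = 2.0 * R * T * S1 + R * T**2 * S2
    dS = (dH - dG) / T

    spacing = (fit.x_data[-1] - fit.x_data[0]) / max(len(fit.x_data) - 1, 1)
    dist = np.min(np.abs(x[:, None] - fit.x_data[None, :]), axis=1)
    constrained = dist <= constrained_spacing_factor * spacing

    return ThermoCurves(
        temperature_K=T, dG=dG, dH=dH, dS=dS, dCp=dCp,
        constrained=constrained, scale=fit.scale,
    )


def q10_curve(fit: FitResult, T_grid: np.ndarray) -> Q10Curve:
    """Q10 and the enthalpy estimate it implies, from the fitted spline.

    ln Q10(T) = S(x(T+10)) - S(x(T)) and dH_Q10 = R T^2 ln(Q10) / 10,
    the enthalpy being anchored at the lower temperature T of the pair.
    Grid points whose upper partner T+10 falls outside the fitted range
    are omitted with a warning rather than extrapolated.
    """
    T = np.asarray(T_grid, dtype=float)
    if np.any(T <= 0):
        raise ValueError("grid temperatures must be positive")
    spline = fit.spline()
    lo, hi = spline.domain
    x_lo = _x_of_T(T, fit.scale)
    x_hi = _x_of_T(T + 10.0, fit.scale)
    tol = 1e-12 * max(abs(lo), abs(hi), 1.0)
    ok = (
        (np.minimum(x_lo, x_hi) >= lo - tol)
        & (np.maximum(x_lo, x_hi) <= hi + tol)
    )
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} grid point(s) omitted from the Q10 curve: "
            "T or T+10 K falls outside the fitted temperature range",
            stacklevel=2,
        )
    T = T[ok]
    ln_q10 = np.asarray(spline(x_hi[ok])) - np.asarray(spline(x_lo[ok]))
    dH_q10 = GAS_CONSTANT * T**2 * ln_q10 / 10.0
    return Q10Curve(temperature_K=T, q10=np.exp(ln_q10), dH_q10=dH_q10)


def dh_from_qdelta(fit: FitResult, T: float, delta: float) -> float:
    """Generalized Q10-style enthalpy with an arbitrary step delta (K).

    dH_Qdelta = R T^2 [S(x(T+delta)) - S(x(T))] / delta; as delta -> 0
    this converges to the spline's own enthalpy estimate, exposing the
    finite-difference bias of the Q10 convention.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    spline = fit.spline()
    ln_q = float(spline(_x_of_T(np.asarray(T + delta), fit.scale))) - float(
        spline(_x_of_T(np.asarray(T, dtype=float), fit.scale))
    )
    return GAS_CONSTANT * T**2 * ln_q / delta
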