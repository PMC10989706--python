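"""Ground-truth two-state gating simulations.

The generator produces van 't Hoff data from a two-state model whose
enthalpy and entropy differences derive from a heat-capacity difference
dCp by the standard integrals

    dH(T) = dH(T0) + \\int_{T0}^{T} dCp(T') dT'
    dS(T) = dS(T0) + \\int_{T0}^{T} dCp(T')/T' dT'

with ln Keq(T) = -dH(T)/(R T) + dS(T)/R.  For constant dCp the integrals
are closed forms; an arbitrary dCp(T) callable is integrated numerically
on a fixed 0.01 K trapezoid grid.  Noise is Gaussian and homoscedastic,
either directly on ln(Keq) or on replicate open probabilities, matching
the Gaussian-residual likelihood that underlies the chi-squared fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from vanthoff.constants import GAS_CONSTANT
from vanthoff.data_model import OpenProbabilityTable, VantHoffSeries, open_prob_from_keq

logger = logging.getLogger(__name__)

__all__ = [
    "TwoStateModelSpec",
    "truth_curves",
    "simulate_lnkeq_series",
    "simulate_open_prob",
    "fig2_pair",
]

#: Standard-error floor substituted when a noiseless series is fitted.
SIGMA_FLOOR: float = 1e-6

#: Step (K) of the trapezoid rule used for callable dCp(T).
_DCP_INTEGRATION_STEP: float = 0.01


@dataclass(frozen=True)
class TwoStateModelSpec:
    """Ground truth for a two-state gating equilibrium.

    Parameters
    ----------
    T0
        Reference temperature in K at which ``dH0`` and ``dS0`` are quoted.
    dH0, dS0
        Enthalpy (J/mol) and entropy (J/(mol K)) differences at ``T0``.
    dCp
        Heat-capacity difference in J/(mol K): a constant, or a callable
        ``dCp(T)`` for temperature-dependent truths.
    sigma_y
        Gaussian noise standard deviation on ln(Keq).
    sigma_P
        Gaussian noise standard deviation on replicate open probabilities.
    n_replicates
        Replicates per temperature in open-probability mode (>= 2).
    """

    T0: float
    dH0: float
    dS0: float
    dCp: float | Callable[[np.ndarray], np.ndarray] = 0.0
    sigma_y: float = 0.0
    sigma_P: float = 0.0
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("reference temperature must be positive")
        if self.sigma_y < 0 or self.sigma_P < 0:
            raise ValueError("noise levels must be non-negative")


def _dcp_integrals(spec: TwoStateModelSpec, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integrals of dCp and dCp/T' from T0 to each T."""
    if callable(spec.dCp):
        shape = T.shape
        T = np.atleast_1d(T)
        out_h = np.empty_like(T)
        out_s = np.empty_like(T)
        for i, t in enumerate(T):
            a, b = (spec.T0, t) if t >= spec.T0 else (t, spec.T0)
            n = max(int(np.ceil((b - a) / _DCP_INTEGRATION_STEP)), 1) + 1
            grid = np.linspace(a, b, n)
            c = np.asarray(spec.dCp(grid), dtype=float)
            ih = np.trapezoid(c, grid)
            is_ = np.trapezoid(c / grid, grid)
            sign = 1.0 if t >= spec.T0 else -1.0
            out_h[i] = sign * ih
            out_s[i] = sign * is_
        return out_h.reshape(shape), out_s.reshape(shape)
    c = float(spec.dCp)
    return c * (T - spec.T0), c * np.log(T / spec.T0)


def truth_curves(spec: TwoStateModelSpec, T) -> dict[str, np.ndarray]:
    """Exact dH(T), dS(T), dG(T) and ln Keq(T) for a model spec."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    int_h, int_s = _dcp_integrals(spec, T)
    dH = spec.dH0 + int_h
    dS = spec.dS0 + int_s
    dG = dH - T * dS
    lnkeq = -dH / (GAS_CONSTANT * T) + dS / GAS_CONSTANT
    return {"dH": dH, "dS": dS, "dG": dG, "lnkeq": lnkeq}


def simulate_lnkeq_series(
    spec: TwoStateModelSpec, T_grid, seed: int | None = None
) -> VantHoffSeries:
    """Simulate a ln(Keq) series with Gaussian noise of width sigma_y.

    The recorded standard errors equal the generating noise level; a
    noiseless spec records the documented floor instead, since downstream
    chi-squared weighting requires positive errors.
    """
    T = np.sort(np.asarray(T_grid, dtype=float))
    truth = truth_curves(spec, T)
    rng = np.random.default_rng(seed)
    y = truth["lnkeq"] + rng.normal(0.0, spec.sigma_y, size=T.shape)
    if spec.sigma_y > 0:
        sigma = np.full_like(T, spec.sigma_y)
    else:
        logger.warning("sigma_y = 0: recording standard-error floor %g", SIGMA_FLOOR)
        sigma = np.full_like(T, SIGMA_FLOOR)
    return VantHoffSeries(T, y, sigma, provenance="synthetic")


def simulate_open_prob(
    spec: TwoStateModelSpec, T_grid, seed: int | None = None
) -> OpenProbabilityTable:
    """Simulate replicate open-probability measurements.

    Each replicate is the true P(T) = Keq/(1+Keq) plus Gaussian noise of
    width sigma_P; draws falling outside (0, 1) are rejected and redrawn,
    which keeps the replicate mean unbiased (truncation would not).
    """
    if spec.n_replicates < 2:
        raise ValueError("open-probability mode needs at least 2 replicates")
    T = np.sort(np.asarray(T_grid, dtype=float))
    truth = truth_curves(spec, T)
    p_true = open_prob_from_keq(np.exp(truth["lnkeq"]))
    rng = np.random.default_rng(seed)
    replicates = []
    n_redraws = 0
    for p in np.atleast_1d(p_true):
        draws = p + rng.normal(0.0, spec.sigma_P, size=spec.n_replicates)
        bad = (draws <= 0.0) | (draws >= 1.0)
        while np.any(bad):
            n_redraws += int(np.sum(bad))
            draws[bad] = p + rng.normal(0.0, spec.sigma_P, size=int(np.sum(bad)))
            bad = (draws <= 0.0) | (draws >= 1.0)
        replicates.append(draws)
    if n_redraws:
        logger.info("redrew %d replicate(s) that fell outside (0, 1)", n_redraws)
    return OpenProbabilityTable(T, tuple(replicates))


def fig2_pair(
    a: float, b: float, c: float, d: float,
    T_grid, sigma: float = 0.0, seed: int | None = None,
) -> tuple[VantHoffSeries, VantHoffSeries]:
    """A linear and a reciprocal series on a shared temperature grid.

    Series one samples f(T) = a + b T, series two g(T) = c - d/T, both
    with the same Gaussian noise level.  On a narrow (physiological)
    temperature range the two are statistically indistinguishable; only a
    range spanning orders of magnitude in T separates them.
    """
    T = np.sort(np.asarray(T_grid, dtype=float))
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    rng = np.random.default_rng(seed)
    sig = sigma if sigma > 0 else SIGMA_FLOOR
    f = a + b * T + rng.normal(0.0, sigma, size=T.shape)
    g = c - d / T + rng.normal(0.0, sigma, size=T.shape)
    mk = lambda y: VantHoffSeries(T, y, np.full_like(T, sig), provenance="synthetic")
    return mk(f), mk(g)
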