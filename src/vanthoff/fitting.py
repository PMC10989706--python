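"""Free-knot spline fitting of van 't Hoff data and BIC model selection.

For a candidate with N spline intervals the free parameters are the N-1
interior knot positions and the N+1 knot values; the edge knots are pinned
to the extremes of the transformed data.  Because a natural cubic
interpolant is linear in its knot values, the values are profiled out
exactly by weighted linear least squares for any trial set of positions
(variable projection), leaving a low-dimensional nonlinear search over the
positions alone.  The position search runs from several starts to guard
against the multimodality that free-knot problems are known for; knot
ordering is maintained by optimizing unconstrained increments that map to
strictly increasing positions with a minimum-separation guarantee.

Candidates over the (knot count, temperature scale) grid are ranked by the
Bayesian information criterion BIC = chi^2_min + 2 N ln(n_points), the
chi-squared statistic being interpreted as twice a Gaussian negative
log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from vanthoff.data_model import VantHoffSeries
from vanthoff.spline import KnotSet, NaturalCubicSpline, MIN_SEPARATION_FRACTION

__all__ = [
    "FitConfig",
    "TransformedData",
    "FitResult",
    "ModelSelectionReport",
    "transform_scale",
    "chi_squared",
    "fit_free_knot_spline",
    "bic",
    "select_model",
]

Scale = Literal["linear", "reciprocal"]


@dataclass(frozen=True)
class FitConfig:
    """Settings for the free-knot fit and the model scan.

    Parameters
    ----------
    scale
        ``"linear"`` (x = T), ``"reciprocal"`` (x = 1/T) or ``"auto"``
        (scan both; on physiological temperature ranges the two are rarely
        distinguishable, so the scan is the default).
    n_max
        Largest interval count N to try; additionally capped so that
        ``n_points >= 2N + 1`` leaves at least one residual degree of
        freedom.
    multistart
        Number of optimizer starts per candidate.  The first start places
        interior knots at evenly spaced x-quantiles; the rest jitter that
        layout with the seeded generator.
    seed
        Seed for every source of randomness in the scan.
    min_sep_frac
        Minimum interior-knot separation as a fraction of the x span.
    tol
        Convergence tolerance passed to the least-squares refiner.
    bic_tie_tol
        BIC differences below this are treated as ties and broken by
        parsimony (smaller N), then by the reciprocal scale.
    """

    scale: Literal["linear", "reciprocal", "auto"] = "auto"
    n_max: int = 8
    multistart: int = 10
    seed: int = 0
    min_sep_frac: float = MIN_SEPARATION_FRACTION
    tol: float = 1e-10
    bic_tie_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")
        if self.multistart < 1:
            raise ValueError("multistart must be at least 1")


@dataclass(frozen=True)
class TransformedData:
    """A series mapped to fit coordinates, sorted ascending in x."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    scale: Scale
    temperature_K: np.ndarray  # aligned with x

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class FitResult:
    """Optimized free-knot spline for one (N, scale) candidate."""

    scale: Scale
    knots: KnotSet
    chi2_min: float
    n_intervals: int
    n_points: int
    bic: float
    converged: bool
    chi2_per_start: tuple[float, ...]
    x_data: np.ndarray

    @property
    def n_params(self) -> int:
        return 2 * self.n_intervals

    def spline(self) -> NaturalCubicSpline:
        return NaturalCubicSpline(self.knots)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "N": self.n_intervals,
            "n_points": self.n_points,
            "chi2_min": self.chi2_min,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "chi2_per_start": list(self.chi2_per_start),
            "knots": {
                "positions": self.knots.positions.tolist(),
                "values": self.knots.values.tolist(),
            },
        }


def transform_scale(series: VantHoffSeries, scale: Scale) -> TransformedData:
    """Map temperatures to the fit coordinate x = T or x = 1/T.

    The reciprocal map reverses the temperature order, so the output is
    re-sorted to ascending x.  Standard errors are untouched: the noise
    model lives on ln(Keq), not on the abscissa.
    """
    T = series.temperature_K
    if scale == "linear":
        x = T.copy()
    elif scale == "reciprocal":
        x = 1.0 / T
    else:
        raise ValueError(f"unknown scale {scale!r}")
    order = np.argsort(x, kind="stable")
    return TransformedData(
        x=x[order], y=series.lnkeq[order], sigma=series.sigma[order],
        scale=scale, temperature_K=T[order],
    )


def chi_squared(data: TransformedData, spline: NaturalCubicSpline) -> float:
    """Weighted sum of squared residuals of the data about the spline."""
    resid = (data.y - np.asarray(spline(data.x))) / data.sigma
    return float(np.dot(resid, resid))


def bic(chi2_min: float, n_intervals: int, n_points: int) -> float:
    """Bayesian information criterion for a 2N-parameter spline candidate.

    ``BIC = chi^2_min + 2 N ln(n_points)``, with n_points the number of
    data points entering the fit.  Requires at least one residual degree
    of freedom (``n_points >= 2N + 1``).
    """
    if n_points <= 2 * n_intervals:
        raise ValueError(
            f"n_points={n_points} leaves no residual degrees of freedom for "
            f"N={n_intervals} (need n_points >= 2N + 1)"
        )
    return float(chi2_min + 2 * n_intervals * np.log(n_points))


# ----------------------------------------------------------------------
# internals: variable projection over interior-knot positions


def _basis_matrix(positions: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Matrix B with B[m, j] = (natural spline through unit value at knot j)(x_m).

    The natural interpolant is linear in its knot values, so
    S(x_m) = sum_j B[m, j] v_j for any value vector v.  The knot second
    derivatives come from the standard tridiagonal system (natural
    boundary rows eliminated), solved banded in O(N) per right-hand side.
    """
    s = np.asarray(positions, dtype=float)
    n = len(s) - 1  # number of intervals
    h = np.diff(s)
    n_knots = n + 1

    # Z maps knot values to knot second derivatives (rows 0 and n are zero).
    Z = np.zeros((n_knots, n_knots))
    if n >= 2:
        # interior equations j = 1..n-1:
        #   h[j-1]/6 M[j-1] + (h[j-1]+h[j])/3 M[j] + h[j]/6 M[j+1]
        #       = (v[j+1]-v[j])/h[j] - (v[j]-v[j-1])/h[j-1]
        m = n - 1
        A = np.zeros((m, m))
        diag = np.arange(m)
        A[diag, diag] = (h[:-1] + h[1:]) / 3.0
        A[diag[:-1], diag[:-1] + 1] = h[1:-1] / 6.0
        A[diag[:-1] + 1, diag[:-1]] = h[1:-1] / 6.0
        rhs = np.zeros((m, n_knots))
        idx = np.arange(1, n)
        rhs[idx - 1, idx - 1] += 1.0 / h[idx - 1]
        rhs[idx - 1, idx] -= 1.0 / h[idx - 1] + 1.0 / h[idx]
        rhs[idx - 1, idx + 1] += 1.0 / h[idx]
        # the system is tridiagonal; at these sizes a dense solve is cheapest
        Z[1:n, :] = np.linalg.solve(A, rhs)

    # locate each x in its interval and assemble the piecewise formula,
    # S(x) = v_i (1-u) + v_{i+1} u + M_i c_i(x) + M_{i+1} d_i(x),
    # which is linear in v through M = Z v.
    i = np.clip(np.searchsorted(s, x, side="right") - 1, 0, n - 1)
    hi = h[i]
    t = x - s[i]
    u = t / hi
    w = hi - t
    c = w**3 / (6.0 * hi) - hi * w / 6.0
    d = t**3 / (6.0 * hi) - hi * t / 6.0

    B = np.zeros((len(x), n_knots))
    rows = np.arange(len(x))
    B[rows, i] += 1.0 - u
    B[rows, i + 1] += u
    B += (c[:, None] * Z[i, :]) + (d[:, None] * Z[i + 1, :])
    return B


def _solve_values(
    positions: np.ndarray, data: TransformedData
) -> tuple[np.ndarray, np.ndarray, float]:
    """Profile out the knot values: weighted linear LS given fixed positions."""
    B = _basis_matrix(positions, data.x)
    A = B / data.sigma[:, None]
    b = data.y / data.sigma
    try:
        # normal equations: the minimum-separation guard keeps the basis
        # well conditioned, and this is much cheaper than an SVD solve
        v = np.linalg.solve(A.T @ A, A.T @ b)
    except np.linalg.LinAlgError:
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ v
    return v, resid, float(np.dot(resid, resid))


def _positions_from_increments(
    u: np.ndarray, lo: float, hi: float, n_intervals: int, min_sep_frac: float
) -> np.ndarray:
    """Map unconstrained increments to strictly increasing interior knots.

    ``u`` holds N-1 free logits; a fixed zero logit for the last interval
    removes the softmax shift degeneracy.  Each interval receives a
    guaranteed floor of ``min_sep_frac`` of the span plus a share of the
    remainder proportional to its softmax weight, so every iterate is
    feasible by construction.
    """
    span = hi - lo
    z = np.concatenate([u, [0.0]])
    z = z - np.max(z)
    w = np.exp(z)
    w /= w.sum()
    widths = span * (min_sep_frac + (1.0 - n_intervals * min_sep_frac) * w)
    s = lo + np.concatenate([[0.0], np.cumsum(widths)])
    s[-1] = hi  # guard against roundoff
    return s


def _increments_from_positions(
    s: np.ndarray, min_sep_frac: float
) -> np.ndarray:
    """Inverse of :func:`_positions_from_increments` (up to roundoff)."""
    lo, hi = s[0], s[-1]
    n = len(s) - 1
    frac = np.diff(s) / (hi - lo)
    w = (frac - min_sep_frac) / (1.0 - n * min_sep_frac)
    w = np.clip(w, 1e-12, None)
    z = np.log(w)
    return z[:-1] - z[-1]


def _insert_knot(positions: np.ndarray) -> np.ndarray:
    """Split the widest interval at its midpoint (one more interval)."""
    gaps = np.diff(positions)
    j = int(np.argmax(gaps))
    new = positions[j] + gaps[j] / 2.0
    return np.sort(np.append(positions, new))


def fit_free_knot_spline(
    series: VantHoffSeries,
    n_intervals: int,
    scale: Scale,
    config: FitConfig | None = None,
    extra_start_positions: tuple[np.ndarray, ...] = (),
) -> FitResult:
    """Minimize chi-squared over the free knots of an N-interval spline.

    Edge knots are pinned to the data extremes in x.  For N = 1 the model
    is a straight line (natural boundary conditions force the single cubic
    piece to have zero curvature) and the fit reduces to one weighted
    linear least-squares solve.  For N > 1 the interior positions are
    optimized by multistart bounded least squares with the knot values
    profiled out exactly at every step.
    """
    config = config or FitConfig()
    n_pts = len(series)
    if n_pts < 2 * n_intervals + 1:
        raise ValueError(
            f"{n_pts} points cannot constrain N={n_intervals} "
            f"(need at least {2 * n_intervals + 1})"
        )
    data = transform_scale(series, scale)
    lo, hi = float(data.x[0]), float(data.x[-1])

    if n_intervals == 1:
        positions = np.array([lo, hi])
        v, _, chi2 = _solve_values(positions, data)
        return FitResult(
            scale=scale, knots=KnotSet(positions, v), chi2_min=chi2,
            n_intervals=1, n_points=n_pts,
            bic=bic(chi2, 1, n_pts), converged=True,
            chi2_per_start=(chi2,), x_data=data.x,
        )

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_free = n_intervals - 1

    # Start 1: interior knots at evenly spaced quantiles of the data x.
    q = np.linspace(0.0, 1.0, n_intervals + 1)[1:-1]
    s_init = np.quantile(data.x, q)
    s_init = np.concatenate([[lo], s_init, [hi]])
    # nudge any coincident quantiles apart before inverting the map
    s_init = _positions_from_increments(
        _increments_from_positions(s_init, config.min_sep_frac),
        lo, hi, n_intervals, config.min_sep_frac,
    )
    u0 = _increments_from_positions(s_init, config.min_sep_frac)

    def residuals(u: np.ndarray) -> np.ndarray:
        s = _positions_from_increments(u, lo, hi, n_intervals, config.min_sep_frac)
        _, resid, _ = _solve_values(s, data)
        return resid

    starts: list[np.ndarray] = [u0]
    for pos in extra_start_positions:
        if len(pos) == n_intervals + 1:
            starts.append(_increments_from_positions(pos, config.min_sep_frac))
    while len(starts) < config.multistart + len(extra_start_positions):
        starts.append(u0 + rng.normal(0.0, 1.0, size=n_free))

    best: tuple[float, np.ndarray] | None = None
    chi2_log: list[float] = []
    any_converged = False
    for u_start in starts:
        try:
            # errstate: trf emits benign invalid-divide warnings when the
            # Jacobian is rank-deficient at a flat residual
            with np.errstate(invalid="ignore", divide="ignore"):
                sol = least_squares(
                    residuals, u_start, method="trf",
                    ftol=config.tol, xtol=config.tol, gtol=None,
                    max_nfev=60 * (n_free + 1),
                )
        except Exception:  # numerical breakdown on one start is not fatal
            chi2_log.append(float("inf"))
            continue
        chi2 = float(2.0 * sol.cost)
        chi2_log.append(chi2)
        any_converged = any_converged or bool(sol.success)
        if best is None or chi2 < best[0]:
            best = (chi2, sol.x)

    if best is None:
        # every start failed: report the flag rather than raising
        s = _positions_from_increments(u0, lo, hi, n_intervals, config.min_sep_frac)
        v, _, chi2 = _solve_values(s, data)
        return FitResult(
            scale=scale, knots=KnotSet(s, v), chi2_min=chi2,
            n_intervals=n_intervals, n_points=n_pts,
            bic=bic(chi2, n_intervals, n_pts), converged=False,
            chi2_per_start=tuple(chi2_log), x_data=data.x,
        )

    chi2_min, u_best = best
    s = _positions_from_increments(u_best, lo, hi, n_intervals, config.min_sep_frac)
    v, _, chi2_min = _solve_values(s, data)
    return FitResult(
        scale=scale, knots=KnotSet(s, v), chi2_min=chi2_min,
        n_intervals=n_intervals, n_points=n_pts,
        bic=bic(chi2_min, n_intervals, n_pts), converged=any_converged,
        chi2_per_start=tuple(chi2_log), x_data=data.x,
    )


@dataclass(frozen=True)
class ModelSelectionReport:
    """All candidate fits over the (N, scale) grid plus the BIC winner."""

    results: tuple[FitResult, ...]
    selected_index: int
    config: FitConfig
    sigma_supplied: bool = True

    @property
    def selected(self) -> FitResult:
        return self.results[self.selected_index]

    def bic_table(self) -> list[dict]:
        return [
            {
                "scale": r.scale,
                "N": r.n_intervals,
                "chi2_min": r.chi2_min,
                "n_params": r.n_params,
                "bic": r.bic,
                "converged": r.converged,
                "selected": i == self.selected_index,
            }
            for i, r in enumerate(self.results)
        ]

    def to_dict(self) -> dict:
        return {
            "candidates": [r.to_dict() for r in self.results],
            "selected_index": self.selected_index,
            "selected": self.selected.to_dict(),
            "sigma_supplied": self.sigma_supplied,
            "bic_comparison": "absolute" if self.sigma_supplied else "relative only",
            "config": {
                "scale": self.config.scale,
                "n_max": self.config.n_max,
                "multistart": self.config.multistart,
                "seed": self.config.seed,
                "min_sep_frac": self.config.min_sep_frac,
                "tol": self.config.tol,
                "bic_tie_tol": self.config.bic_tie_tol,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


_SCALE_TIEBREAK = {"reciprocal": 0, "linear": 1}


def select_model(
    series: VantHoffSeries,
    config: FitConfig | None = None,
    sigma_supplied: bool = True,
) -> ModelSelectionReport:
    """Fit every (N, scale) candidate and pick the minimum-BIC model.

    Ties within ``config.bic_tie_tol`` are broken first by smaller N
    (parsimony), then in favor of the reciprocal scale, the conventional
    van 't Hoff abscissa.  The full BIC table is always retained so the
    selection is auditable.
    """
    config = config or FitConfig()
    n_pts = len(series)
    if n_pts < 3:
        raise ValueError("model selection needs at least 3 data points")
    n_cap = min(config.n_max, (n_pts - 1) // 2)
    scales: tuple[Scale, ...]
    scales = ("linear", "reciprocal") if config.scale == "auto" else (config.scale,)

    results: list[FitResult] = []
    prev_best: dict[Scale, FitResult] = {}
    for n_int in range(1, n_cap + 1):
        for scale in scales:
            # warm-start from the previous N's optimum with one knot inserted:
            # the enlarged family contains that optimum exactly, so chi2_min
            # is non-increasing in N by construction.
            warm: tuple[np.ndarray, ...] = ()
            if scale in prev_best:
                warm = (_insert_knot(prev_best[scale].knots.positions),)
            res = fit_free_knot_spline(
                series, n_int, scale, config, extra_start_positions=warm
            )
            results.append(res)
            if scale not in prev_best or res.chi2_min <= prev_best[scale].chi2_min:
                prev_best[scale] = res

    best_bic = min(r.bic for r in results)
    tied = [i for i, r in enumerate(results) if r.bic <= best_bic + config.bic_tie_tol]
    selected = min(tied, key=lambda i: (results[i].n_intervals, _SCALE_TIEBREAK[results[i].scale]))
    return ModelSelectionReport(
        results=tuple(results), selected_index=selected,
        config=config, sigma_supplied=sigma_supplied,
    )
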