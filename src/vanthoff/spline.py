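"""Natural cubic splines parameterized by their knot coordinates.

A spline is specified entirely by knot positions ``s_0 < ... < s_N`` and
knot values ``S(s_i)``: with the natural boundary conditions
``S''(s_0) = S''(s_N) = 0`` there is a unique twice continuously
differentiable piecewise cubic through those coordinates.  The piecewise
coefficients are derived quantities, recomputed from the knots on demand,
which keeps the fit parameterization at 2N numbers (N-1 interior positions
plus N+1 values) and every ordering constraint local.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline as _SciPyCubicSpline

__all__ = ["KnotSet", "NaturalCubicSpline", "build_natural_spline", "MIN_SEPARATION_FRACTION"]

#: Minimum allowed knot separation as a fraction of the knot span.
MIN_SEPARATION_FRACTION: float = 1e-3


@dataclass(frozen=True)
class KnotSet:
    """Strictly increasing knot positions with the spline values there."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.ndim != 1 or v.ndim != 1 or len(s) != len(v):
            raise ValueError("positions and values must be 1-d arrays of equal length")
        if len(s) < 2:
            raise ValueError("a spline needs at least two knots (one interval)")
        gaps = np.diff(s)
        if np.any(gaps <= 0):
            raise ValueError("knot positions must be strictly increasing")
        span = s[-1] - s[0]
        if np.any(gaps < MIN_SEPARATION_FRACTION * span * (1 - 1e-12)):
            raise ValueError(
                f"knots closer than {MIN_SEPARATION_FRACTION:g} of the span; "
                "nearly coincident knots make the interpolant ill-conditioned"
            )
        object.__setattr__(self, "positions", s)
        object.__setattr__(self, "values", v)

    @property
    def n_intervals(self) -> int:
        return len(self.positions) - 1


class NaturalCubicSpline:
    """The unique natural cubic interpolant through a :class:`KnotSet`.

    Evaluation outside ``[s_0, s_N]`` raises: the edge knots are pinned to
    the data extremes during fitting, so extrapolation is never meaningful
    and silently returning it would hide a bug.
    """

    def __init__(self, knots: KnotSet):
        self.knots = knots
        self._pp = _SciPyCubicSpline(
            knots.positions, knots.values, bc_type="natural", extrapolate=False
        )

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots.positions[0]), float(self.knots.positions[-1])

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise coefficients ``a[n, i]`` of ``sum_n a[n, i] (x - s_i)**n``.

        Shape ``(4, N)`` with ascending powers along the first axis.
        """
        return self._pp.c[::-1].copy()

    def __call__(self, x, order: int = 0):
        if order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        tol = 1e-12 * max(abs(lo), abs(hi), 1.0)
        if np.any(x < lo - tol) or np.any(x > hi + tol):
            raise ValueError(f"evaluation outside the spline domain [{lo:g}, {hi:g}]")
        out = self._pp(np.clip(x, lo, hi), nu=order)
        return out if out.ndim else float(out)

    def second_derivatives_at_knots(self) -> np.ndarray:
        return np.asarray(self(self.knots.positions, order=2))

    # -- serialization: knots only, coefficients are recomputed on load ----

    def to_dict(self) -> dict:
        return {
            "positions": self.knots.positions.tolist(),
            "values": self.knots.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalCubicSpline":
        return cls(KnotSet(np.asarray(d["positions"]), np.asarray(d["values"])))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NaturalCubicSpline":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:
        lo, hi = self.domain
        return f"NaturalCubicSpline({self.knots.n_intervals} intervals on [{lo:g}, {hi:g}])"


def build_natural_spline(knots: KnotSet) -> NaturalCubicSpline:
    """Construct the unique natural cubic spline through the given knots."""
    return NaturalCubicSpline(knots)
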