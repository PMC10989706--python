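"""Domain containers and table I/O for van 't Hoff data.

Two kinds of input are supported: a ready-made series of ln(Keq) values with
standard errors, and a long-format table of replicate open-probability
measurements.  Replicate tables are reduced to a :class:`VantHoffSeries` by
the logit transform Keq = P/(1-P) together with first-order (delta-method)
error propagation of the replicate scatter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from vanthoff.constants import CELSIUS_OFFSET

logger = logging.getLogger(__name__)

__all__ = [
    "OpenProbabilityTable",
    "VantHoffSeries",
    "keq_from_open_prob",
    "open_prob_from_keq",
    "lnkeq_from_replicates",
    "read_series",
]


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass(frozen=True)
class VantHoffSeries:
    """Measurements of ln(Keq) with standard errors on a temperature grid.

    Parameters
    ----------
    temperature_K
        Absolute temperatures in Kelvin, strictly increasing.
    lnkeq
        Observed ln(Keq) values (dimensionless), finite.
    sigma
        Standard errors of ``lnkeq``, strictly positive.
    source_unit
        Temperature unit of the original table (``"K"`` or ``"C"``).
    provenance
        ``"lnkeq"`` if the values were supplied directly, ``"open_prob"``
        if they were derived from replicate open probabilities.
    """

    temperature_K: np.ndarray
    lnkeq: np.ndarray
    sigma: np.ndarray
    source_unit: str = "K"
    provenance: str = "lnkeq"
    sigma_supplied: bool = True

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature_K, dtype=float)
        y = np.asarray(self.lnkeq, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if not (T.ndim == y.ndim == s.ndim == 1) or not (len(T) == len(y) == len(s)):
            raise ValidationError("temperature, lnkeq and sigma must be 1-d and equal length")
        if np.any(T <= 0):
            raise ValidationError("absolute temperatures must be positive")
        order = np.argsort(T, kind="stable")
        T, y, s = T[order], y[order], s[order]
        if np.any(np.diff(T) <= 0):
            raise ValidationError("temperatures must be unique")
        if not np.all(np.isfinite(y)):
            raise ValidationError("lnKeq values must be finite")
        bad = np.flatnonzero(~(s > 0) | ~np.isfinite(s))
        if bad.size:
            raise ValidationError(
                f"standard errors must be positive and finite (offending rows: {bad.tolist()})"
            )
        object.__setattr__(self, "temperature_K", T)
        object.__setattr__(self, "lnkeq", y)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return len(self.temperature_K)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature": self.temperature_K, "lnKeq": self.lnkeq, "sigma": self.sigma}
        )


@dataclass(frozen=True)
class OpenProbabilityTable:
    """Replicate open-probability measurements per temperature.

    ``replicates[i]`` holds the open probabilities measured at
    ``temperature_K[i]``; replicate counts may differ between temperatures.
    """

    temperature_K: np.ndarray
    replicates: tuple[np.ndarray, ...]
    source_unit: str = "K"

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature_K, dtype=float)
        reps = tuple(np.asarray(r, dtype=float) for r in self.replicates)
        if len(T) != len(reps):
            raise ValidationError("one replicate array is required per temperature")
        if np.any(T <= 0):
            raise ValidationError("absolute temperatures must be positive")
        if np.any(np.diff(T) <= 0):
            raise ValidationError("temperatures must be strictly increasing and unique")
        for i, r in enumerate(reps):
            if r.ndim != 1 or r.size == 0:
                raise ValidationError(f"row {i}: replicates must be a non-empty 1-d array")
            if np.any((r <= 0) | (r >= 1)):
                raise ValidationError(
                    f"row {i} (T={T[i]:g} K): open probabilities must lie strictly in (0, 1)"
                )
        object.__setattr__(self, "temperature_K", T)
        object.__setattr__(self, "replicates", reps)

    def __len__(self) -> int:
        return len(self.temperature_K)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with one row per (temperature, replicate)."""
        rows = [
            (t, p)
            for t, reps in zip(self.temperature_K, self.replicates)
            for p in reps
        ]
        return pd.DataFrame(rows, columns=["temperature", "open_prob"])


def keq_from_open_prob(p):
    """Two-state equilibrium constant Keq = P/(1-P) for open probability P.

    Strictly increasing on (0, 1); raises for arguments on or outside the
    boundary, where Keq is undefined or infinite.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("open probability must lie strictly in (0, 1)")
    out = p / (1.0 - p)
    return out if out.ndim else float(out)


def open_prob_from_keq(keq):
    """Inverse of :func:`keq_from_open_prob`: P = Keq/(1+Keq)."""
    keq = np.asarray(keq, dtype=float)
    if np.any(keq <= 0):
        raise ValueError("equilibrium constant must be positive")
    out = keq / (1.0 + keq)
    return out if out.ndim else float(out)


def lnkeq_from_replicates(
    table: OpenProbabilityTable,
    p_bounds: tuple[float, float] | None = (0.01, 0.99),
) -> VantHoffSeries:
    """Reduce replicate open probabilities to ln(Keq) with standard errors.

    For each temperature with mean open probability ``P̄`` and unbiased
    sample variance ``s²`` over ``N`` replicates,

    .. math::

        y = \\ln\\frac{\\bar P}{1-\\bar P}, \\qquad
        \\sigma_y = \\sqrt{\\frac{1}{N}\\,
            \\Big(\\frac{1}{\\bar P - \\bar P^2}\\Big)^2 s^2},

    which is the delta-method propagation of the standard error of the mean
    through the logit transform.

    Parameters
    ----------
    table
        Replicate measurements; every temperature needs at least two
        replicates so that a sample variance exists.
    p_bounds
        Mean open probabilities outside ``(p_min, p_max)`` are dropped with
        a logged warning.  Near-saturating probabilities are dominated by
        noise sources unrelated to gating, so trimming the extremes is
        usually advisable.  Pass ``None`` to keep every temperature.
    """
    T_keep, y_keep, s_keep = [], [], []
    for t, reps in zip(table.temperature_K, table.replicates):
        n = reps.size
        if n < 2:
            raise ValidationError(
                f"T={t:g} K has a single replicate; at least two are required "
                "to estimate a standard error"
            )
        pbar = float(np.mean(reps))
        if p_bounds is not None and not (p_bounds[0] < pbar < p_bounds[1]):
            logger.warning(
                "dropping T=%g K: mean open probability %.4g outside bounds (%g, %g)",
                t, pbar, p_bounds[0], p_bounds[1],
            )
            warnings.warn(
                f"dropping T={t:g} K: mean open probability {pbar:.4g} outside "
                f"p_bounds ({p_bounds[0]:g}, {p_bounds[1]:g})",
                stacklevel=2,
            )
            continue
        if not (0.0 < pbar < 1.0):
            raise ValidationError(f"T={t:g} K: mean open probability {pbar} not in (0, 1)")
        var = float(np.var(reps, ddof=1))
        # roundoff can leave ~1e-32 where the variance is really zero
        if var <= (1e-12 * max(pbar, 1.0 - pbar)) ** 2:
            raise ValidationError(
                f"T={t:g} K: replicates are identical, so the propagated standard "
                "error vanishes; supply sigma directly or add replicates"
            )
        sigma = np.sqrt(var / n) / (pbar - pbar * pbar)
        T_keep.append(t)
        y_keep.append(np.log(pbar / (1.0 - pbar)))
        s_keep.append(sigma)
    if not T_keep:
        raise ValidationError("all temperatures were filtered out by p_bounds")
    return VantHoffSeries(
        np.asarray(T_keep), np.asarray(y_keep), np.asarray(s_keep),
        source_unit=table.source_unit, provenance="open_prob",
    )


# Column-name aliases accepted when mapping a header onto canonical names.
_ALIASES = {
    "temperature": {"temperature", "temp", "t", "t_k", "t_c", "temperature_k", "temperature_c"},
    "lnKeq": {"lnkeq", "ln_keq", "log_keq", "lnk", "y"},
    "sigma": {"sigma", "se", "stderr", "std_err", "sigma_lnkeq"},
    "open_prob": {"open_prob", "p", "popen", "p_open", "open_probability"},
}


def _resolve_columns(header: Sequence[str], mapping: dict[str, str] | None) -> dict[str, str]:
    resolved: dict[str, str] = {}
    lower = {c.lower().strip(): c for c in header}
    mapping = mapping or {}
    for canon, aliases in _ALIASES.items():
        if canon in mapping:
            if mapping[canon] not in header:
                raise ValidationError(f"mapped column {mapping[canon]!r} not found in header")
            resolved[canon] = mapping[canon]
            continue
        hits = [lower[a] for a in aliases if a in lower]
        if len(hits) > 1:
            raise ValidationError(f"ambiguous columns for {canon!r}: {hits}")
        if hits:
            resolved[canon] = hits[0]
    return resolved


def read_series(
    path: str | Path,
    *,
    temperature_unit: str = "K",
    columns: dict[str, str] | None = None,
    delimiter: str | None = None,
    p_bounds: tuple[float, float] | None = (0.01, 0.99),
    convert: bool = True,
):
    """Read a delimited text table of van 't Hoff data.

    The header decides the interpretation: ``temperature, lnKeq, sigma``
    yields a :class:`VantHoffSeries` directly, while ``temperature,
    open_prob`` (long format, repeated temperature rows for replicates) is
    reduced through :func:`lnkeq_from_replicates` when ``convert`` is true
    and returned as an :class:`OpenProbabilityTable` otherwise.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    temperature_unit
        ``"K"`` or ``"C"``; Celsius temperatures are converted to Kelvin.
        The unit is never guessed from the numbers.
    columns
        Optional mapping from canonical names (``temperature``, ``lnKeq``,
        ``sigma``, ``open_prob``) to the actual header names.
    delimiter
        Field delimiter; sniffed by pandas when omitted.
    p_bounds
        Passed to :func:`lnkeq_from_replicates` for open-probability input;
        ignored for direct ln(Keq) input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if temperature_unit not in {"K", "C"}:
        raise ValueError("temperature_unit must be 'K' or 'C'")
    df = pd.read_csv(path, sep=delimiter, engine="python", skipinitialspace=True)
    cols = _resolve_columns(list(df.columns), columns)
    if "temperature" not in cols:
        raise ValidationError(f"no temperature column found in header {list(df.columns)}")

    t_raw = pd.to_numeric(df[cols["temperature"]], errors="coerce")
    if t_raw.isna().any():
        raise ValidationError(
            f"non-numeric temperature in rows {t_raw.index[t_raw.isna()].tolist()}"
        )
    T = t_raw.to_numpy(dtype=float)
    if temperature_unit == "C":
        T = T + CELSIUS_OFFSET

    if "lnKeq" in cols:
        y = pd.to_numeric(df[cols["lnKeq"]], errors="coerce").to_numpy(dtype=float)
        if "sigma" in cols:
            s = pd.to_numeric(df[cols["sigma"]], errors="coerce").to_numpy(dtype=float)
            sigma_supplied = True
        else:
            # no error column: unit weights; downstream BIC comparisons are
            # then only meaningful relative to one another
            logger.warning("no sigma column found; using unit weights")
            s = np.ones_like(y)
            sigma_supplied = False
        if np.any(np.isnan(y)) or np.any(np.isnan(s)):
            raise ValidationError("non-numeric lnKeq or sigma values")
        order = np.argsort(T, kind="stable")
        return VantHoffSeries(
            T[order], y[order], s[order],
            source_unit=temperature_unit, provenance="lnkeq",
            sigma_supplied=sigma_supplied,
        )

    if "open_prob" in cols:
        p = pd.to_numeric(df[cols["open_prob"]], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(p)):
            raise ValidationError("non-numeric open-probability values")
        uniq = np.unique(T)
        reps = tuple(p[T == t] for t in uniq)
        table = OpenProbabilityTable(uniq, reps, source_unit=temperature_unit)
        if convert:
            return lnkeq_from_replicates(table, p_bounds=p_bounds)
        return table

    # wide replicate format: one row per temperature, remaining numeric
    # columns hold individual replicate measurements of P
    rep_cols = [c for c in df.columns if c != cols["temperature"]]
    if rep_cols:
        if len(np.unique(T)) != len(T):
            raise ValidationError("duplicate temperatures in wide-format table")
        vals = df[rep_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            raise ValidationError("wide-format replicate columns are entirely non-numeric")
        order = np.argsort(T, kind="stable")
        reps = tuple(row[~np.isnan(row)] for row in vals[order])
        if any(r.size == 0 for r in reps):
            raise ValidationError("a wide-format row has no numeric replicates")
        table = OpenProbabilityTable(T[order], reps, source_unit=temperature_unit)
        if convert:
            return lnkeq_from_replicates(table, p_bounds=p_bounds)
        return table

    raise ValidationError(
        f"header {list(df.columns)} matches neither (temperature, lnKeq[, sigma]) "
        "nor (temperature, open_prob) nor a wide replicate table"
    )
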