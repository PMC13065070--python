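"""Compositional-data primitives for 24-hour time-use analysis.

A day's time use is a *composition*: a vector of non-negative minutes per
behaviour set that carries only relative information and is closed to a fixed
total of 1440 min. This module provides the standard CoDA toolkit needed by
the rest of the package:

* closure (rescaling to the fixed total),
* multiplicative replacement of zeros,
* the compositional (closed geometric) mean,
* isometric log-ratio (ILR) transforms via pivot (sequential binary
  partition) bases, and their inverse,
* subcompositions and percentage summaries.

Single compositions are represented as :class:`pandas.Series` indexed by part
name; samples as :class:`pandas.DataFrame` with one part per column. All
functions also accept plain arrays where part names are not needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    PreconditionError,
)

MINUTES_PER_DAY = 1440.0

#: Behaviour sets used for weekday diaries, in canonical order.
WEEKDAY_PARTS: tuple[str, ...] = (
    "sleep",
    "physical_activity",
    "media",
    "school",
    "hobbies",
    "domestic",
)

#: Behaviour sets used for weekend diaries (physical activity and
#: school-related time are too scarce at weekends to support reallocations
#: and are removed by subcomposition).
WEEKEND_PARTS: tuple[str, ...] = ("sleep", "media", "hobbies", "domestic")

CLOSURE_TOL = 1e-6
ROUNDTRIP_TOL = 1e-9
ORTHONORMALITY_TOL = 1e-10


def _as_values(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _like(template, values: np.ndarray):
    """Return *values* wrapped like *template* (Series/DataFrame passthrough)."""
    if isinstance(template, pd.Series):
        return pd.Series(values, index=template.index, name=template.name)
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(values, index=template.index, columns=template.columns)
    return values


def closure(parts, total: float = MINUTES_PER_DAY):
    """Rescale non-negative parts so they sum to *total* (default 1440 min).

    Works on a single composition (1-D) or row-wise on a sample (2-D /
    DataFrame). Raises :class:`DegenerateInputError` if any composition is
    all-zero, and :class:`DomainError` on negative parts.
    """
    v = _as_values(parts)
    if np.any(v < 0):
        raise DomainError("compositional parts must be non-negative")
    s = v.sum(axis=-1, keepdims=v.ndim > 1)
    if np.any(np.asarray(s) <= 0):
        raise DegenerateInputError("cannot close an all-zero composition")
    return _like(parts, v * (total / s))


def multiplicative_zero_replace(x, impute: float = 5.0, total: float = MINUTES_PER_DAY):
    """Replace zero parts with *impute* minutes, multiplicatively rescaling.

    Zero parts are set to ``impute``; non-zero parts are multiplied by
    ``(total - impute*z) / total`` where ``z`` counts the zeros, so the output
    still sums to *total* and ratios among originally non-zero parts are
    preserved exactly. Diary zeros are structural (a behaviour can be absent
    at 10-minute resolution) but log-ratios cannot accommodate them, hence
    this standard multiplicative treatment with a small value below the slot
    resolution.

    Input must already be closed to *total*. ``impute`` must lie in (0, 10):
    the replacement value must stay below the 10-minute slot resolution.
    """
    if not (0 < impute < 10):
        raise ConfigurationError(
            f"impute must lie strictly between 0 and 10 minutes, got {impute}"
        )
    v = _as_values(x)
    if np.any(v < 0):
        raise DomainError("compositional parts must be non-negative")
    sums = v.sum(axis=-1)
    if np.any(np.abs(np.asarray(sums) - total) > CLOSURE_TOL):
        raise PreconditionError(
            f"input must be closed to {total} before zero replacement"
        )
    if np.all(v.sum(axis=-1, keepdims=v.ndim > 1) == 0):
        raise DegenerateInputError("all-zero composition")
    zero = v == 0
    z = zero.sum(axis=-1, keepdims=v.ndim > 1)
    scale = (total - impute * z) / total
    out = np.where(zero, impute, v * scale)
    return _like(x, out)


def compositional_mean(xs, total: float = MINUTES_PER_DAY):
    """Closed geometric mean: part-wise geometric mean, re-closed to *total*.

    *xs* is a DataFrame / 2-D array of strictly positive compositions (apply
    zero replacement first).
    """
    v = _as_values(xs)
    if v.ndim != 2 or v.shape[0] == 0:
        raise PreconditionError("need a non-empty 2-D sample of compositions")
    if np.any(v <= 0):
        raise PreconditionError(
            "compositional mean requires strictly positive parts; replace zeros first"
        )
    gm = np.exp(np.log(v).mean(axis=0))
    closed = gm * (total / gm.sum())
    if isinstance(xs, pd.DataFrame):
        return pd.Series(closed, index=xs.columns)
    return closed


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal ILR contrast basis for a D-part composition.

    ``V`` is the D x (D-1) contrast matrix (rows ordered as ``parts``);
    columns are orthonormal and orthogonal to the all-ones vector, so
    ``z = V' ln(x)`` is invariant to the scale of ``x``.
    """

    V: np.ndarray
    parts: tuple[str, ...]
    pivot_order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        V = np.asarray(self.V, dtype=float)
        D = len(self.parts)
        if V.shape != (D, D - 1):
            raise ConfigurationError(f"contrast matrix must be {D}x{D - 1}")
        if np.max(np.abs(V.T @ V - np.eye(D - 1))) > ORTHONORMALITY_TOL:
            raise ConfigurationError("ILR basis columns are not orthonormal")
        if np.max(np.abs(V.sum(axis=0))) > ORTHONORMALITY_TOL:
            raise ConfigurationError("ILR basis columns must sum to zero")
        object.__setattr__(self, "V", V)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def n_coordinates(self) -> int:
        return len(self.parts) - 1

    def coordinate_names(self) -> list[str]:
        order = self.pivot_order or self.parts
        return [f"ilr{j + 1}_{order[j]}" for j in range(self.n_coordinates)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=list(self.parts), columns=self.coordinate_names())


def make_pivot_basis(parts: Sequence[str] | int, pivot_order: Sequence[str] | None = None) -> IlrBasis:
    """Build the pivot (sequential binary partition) ILR basis.

    Coordinate ``j`` (1-based) contrasts the j-th part of *pivot_order*
    against all later parts, with normalising constant
    ``sqrt((D-j)/(D-j+1))``; the first coordinate therefore captures one
    behaviour relative to the geometric mean of all the others. Rows of the
    returned matrix follow the original *parts* order, so the same data
    columns can be used with any pivot order.

    *parts* may be an integer D, in which case parts are named ``p1..pD``.
    """
    if isinstance(parts, int):
        parts = tuple(f"p{i + 1}" for i in range(parts))
    else:
        parts = tuple(parts)
    D = len(parts)
    if D < 2:
        raise ConfigurationError("need at least two parts for an ILR basis")
    if pivot_order is None:
        pivot_order = parts
    else:
        pivot_order = tuple(pivot_order)
        if sorted(pivot_order) != sorted(parts):
            raise ConfigurationError(
                f"pivot_order must be a permutation of the parts {parts}, got {pivot_order}"
            )
    perm = [parts.index(p) for p in pivot_order]
    Vp = np.zeros((D, D - 1))
    for j in range(D - 1):
        r = D - j - 1  # number of parts in the denominator group
        c = np.sqrt(r / (r + 1))
        Vp[j, j] = c
        Vp[j + 1:, j] = -c / r
    V = np.zeros_like(Vp)
    V[perm, :] = Vp
    return IlrBasis(V=V, parts=parts, pivot_order=pivot_order)


def _aligned(x, basis: IlrBasis) -> np.ndarray:
    """Values of *x* in the basis' part order."""
    if isinstance(x, pd.Series):
        missing = set(basis.parts) - set(x.index)
        if missing:
            raise ConfigurationError(f"composition lacks parts {sorted(missing)}")
        return x.reindex(list(basis.parts)).to_numpy(dtype=float)
    if isinstance(x, pd.DataFrame):
        missing = set(basis.parts) - set(x.columns)
        if missing:
            raise ConfigurationError(f"sample lacks part columns {sorted(missing)}")
        return x.loc[:, list(basis.parts)].to_numpy(dtype=float)
    return _as_values(x)


def ilr(x, basis: IlrBasis) -> np.ndarray:
    """ILR coordinates ``z = V' ln(x)``.

    Scale-invariant (``ilr(x) == ilr(closure(x))``), so the input need not be
    closed; it must be strictly positive. Returns a 1-D array of D-1
    coordinates, or an (n, D-1) array for a sample.
    """
    v = _aligned(x, basis)
    if np.any(v <= 0):
        raise DomainError(
            "ILR requires strictly positive parts; apply multiplicative zero "
            "replacement first"
        )
    return np.log(v) @ basis.V


def ilr_inverse(z, basis: IlrBasis, total: float = MINUTES_PER_DAY):
    """Map ILR coordinates back to a composition closed to *total*."""
    zv = _as_values(z)
    if not np.all(np.isfinite(zv)):
        raise DomainError("ILR coordinates must be finite")
    logx = zv @ basis.V.T
    # subtract the row max before exponentiating: closure removes the shift
    shift = logx.max(axis=-1, keepdims=logx.ndim > 1)
    x = np.exp(logx - shift)
    if not np.all(np.isfinite(x)):
        raise DomainError("numeric overflow inverting ILR coordinates")
    closed = x * (total / x.sum(axis=-1, keepdims=x.ndim > 1))
    if zv.ndim == 1:
        return pd.Series(closed, index=list(basis.parts))
    return pd.DataFrame(closed, columns=list(basis.parts))


def subcomposition(x, keep: Iterable[str], total: float = MINUTES_PER_DAY):
    """Keep the named parts and re-close to *total*.

    Used for the weekend analysis, where physical activity and school-related
    time are removed and the remaining four sets are re-closed to 1440 min.
    """
    keep = list(keep)
    if not keep:
        raise ConfigurationError("subcomposition needs a non-empty set of parts")
    if isinstance(x, pd.Series):
        missing = set(keep) - set(x.index)
        if missing:
            raise ConfigurationError(f"unknown parts in keep: {sorted(missing)}")
        return closure(x.loc[keep], total=total)
    if isinstance(x, pd.DataFrame):
        missing = set(keep) - set(x.columns)
        if missing:
            raise ConfigurationError(f"unknown parts in keep: {sorted(missing)}")
        return closure(x.loc[:, keep], total=total)
    raise ConfigurationError("subcomposition needs named parts (Series or DataFrame)")


def part_percentages(x, total: float = MINUTES_PER_DAY) -> pd.Series:
    """Percent of the day per part, rounded to the nearest whole percent."""
    v = _as_values(x)
    if abs(v.sum() - total) > CLOSURE_TOL:
        raise PreconditionError(f"composition must be closed to {total}")
    pct = np.rint(100.0 * v / total).astype(int)
    if isinstance(x, pd.Series):
        return pd.Series(pct, index=x.index)
    return pd.Series(pct)
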