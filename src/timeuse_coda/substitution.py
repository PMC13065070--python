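"""Compositional isotemporal substitution.

Given a fitted outcome model and a base composition (by default the sample's
compositional mean), a substitution moves Delta minutes from one behaviour
set to another within the fixed 1440-minute day and reports the predicted
outcome difference. Because the model is linear in ILR coordinates, the
difference is the linear contrast ``a . beta_ilr`` with
``a = ilr(substituted) - ilr(base)``; covariate terms cancel exactly. Its
standard error is the delta-method (Wald) form ``sqrt(a' Sigma_ilr a)`` and
the 95% CI uses the t distribution with the model's residual df.

Estimates are deliberately not symmetrised: on the simplex, moving time
*into* a scarce behaviour is not the mirror image of moving time *out* of
it, so beta(add A, remove B) need not equal -beta(add B, remove A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from . import coda
from .coda import IlrBasis, MINUTES_PER_DAY
from .errors import ConfigurationError, InfeasibleReallocationError
from .model import FittedOutcomeModel


@dataclass(frozen=True)
class SubstitutionSpec:
    """Reallocate *delta* minutes into *add_part*, out of *remove_part*."""

    add_part: str
    remove_part: str
    delta: float

    def __post_init__(self):
        if self.add_part == self.remove_part:
            raise ConfigurationError("add_part and remove_part must differ")


@dataclass(frozen=True)
class SubstitutionEstimate:
    add_part: str
    remove_part: str
    delta: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def substitute(base: pd.Series, spec: SubstitutionSpec) -> pd.Series:
    """Move ``spec.delta`` minutes from ``remove_part`` into ``add_part``.

    All other parts are untouched, so the result still sums to 1440. Every
    part of the substituted composition must remain strictly positive (ILR
    needs positivity); otherwise the reallocation is infeasible — this is
    exactly why scarce behaviour sets are dropped from the weekend analysis.
    """
    for part in (spec.add_part, spec.remove_part):
        if part not in base.index:
            raise ConfigurationError(f"part {part!r} not in composition")
    if (base <= 0).any():
        raise InfeasibleReallocationError(
            "base composition must be strictly positive (replace zeros first)"
        )
    out = base.astype(float).copy()
    out[spec.add_part] += spec.delta
    out[spec.remove_part] -= spec.delta
    bad = out[out <= 0]
    if not bad.empty:
        raise InfeasibleReallocationError(
            f"reallocating {spec.delta} min from {spec.remove_part!r} to "
            f"{spec.add_part!r} drives parts to zero or below: "
            f"{dict(bad.round(2))}"
        )
    return out


def predicted_difference(
    model: FittedOutcomeModel,
    base: pd.Series,
    spec: SubstitutionSpec,
    level: float = 0.95,
) -> SubstitutionEstimate:
    """Predicted outcome difference for one reallocation, with Wald CI.

    ``beta = a . beta_ilr`` and ``se = sqrt(a' Sigma_ilr a)`` where ``a`` is
    the ILR displacement of the substitution and ``Sigma_ilr`` the ILR block
    of the coefficient covariance; the CI is ``beta +/- t(1-(1-level)/2,
    residual_df) * se``. Covariate terms cancel in the difference and never
    enter. The estimate is invariant to the pivot order of the basis.
    """
    missing = set(model.basis.parts) - set(base.index)
    if missing:
        raise ConfigurationError(
            f"base composition lacks model parts {sorted(missing)}"
        )
    z0 = coda.ilr(base, model.basis)
    z1 = coda.ilr(substitute(base, spec), model.basis)
    a = z1 - z0
    beta = float(a @ model.beta_ilr)
    se = float(np.sqrt(max(a @ model.cov_ilr @ a, 0.0)))
    tcrit = float(scipy.stats.t.ppf(1.0 - (1.0 - level) / 2.0, model.residual_df))
    ci_low, ci_high = beta - tcrit * se, beta + tcrit * se
    significant = not (ci_low <= 0.0 <= ci_high)
    return SubstitutionEstimate(
        add_part=spec.add_part,
        remove_part=spec.remove_part,
        delta=spec.delta,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
    )


def _estimate_row(model, base, add, remove, delta) -> dict:
    try:
        est = predicted_difference(model, base, SubstitutionSpec(add, remove, delta))
        return {
            "add": add,
            "remove": remove,
            "delta": delta,
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "significant": est.significant,
            "feasible": True,
        }
    except InfeasibleReallocationError:
        return {
            "add": add,
            "remove": remove,
            "delta": delta,
            "beta": np.nan,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "significant": False,
            "feasible": False,
        }


def pairwise_table(
    model: FittedOutcomeModel, base: pd.Series, delta: float
) -> pd.DataFrame:
    """One row per ordered (add, remove) pair at a fixed *delta*.

    D parts yield D(D-1) rows (30 for the six weekday sets, 12 for the four
    weekend sets). Infeasible reallocations are flagged, not fatal.
    """
    parts = list(model.basis.parts)
    rows = [
        _estimate_row(model, base, add, remove, delta)
        for add in parts
        for remove in parts
        if add != remove
    ]
    return pd.DataFrame(rows)


def substitution_grid(
    model: FittedOutcomeModel,
    base: pd.Series,
    delta_max: float,
    step: float = 5.0,
) -> pd.DataFrame:
    """Estimates for every ordered pair over Delta in {-delta_max..+delta_max}.

    The grid steps by *step* minutes and always includes Delta = 0 (where the
    estimate is identically zero). Infeasible cells are flagged.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    k = delta_max / step
    if abs(k - round(k)) > 1e-9:
        raise ConfigurationError("delta_max must be a multiple of step")
    k = int(round(k))
    deltas = [i * step for i in range(-k, k + 1)]
    parts = list(model.basis.parts)
    rows = [
        _estimate_row(model, base, add, remove, d)
        for add in parts
        for remove in parts
        if add != remove
        for d in deltas
    ]
    return pd.DataFrame(rows)


def percent_of_mean(beta: float, outcome_mean: float) -> float:
    """A substitution effect as a percentage of the mean outcome."""
    if outcome_mean == 0:
        raise ConfigurationError("outcome mean must be non-zero")
    return 100.0 * beta / outcome_mean
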