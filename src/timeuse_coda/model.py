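"""Covariate-adjusted linear modelling of attainment on ILR coordinates.

The analysis model is ordinary least squares of the outcome (Attainment 8,
0-90, or number of GCSE passes) on the D-1 ILR coordinates of the time-use
composition plus treatment-coded covariate dummies (sex, ethnicity,
free-school-meals eligibility, maternal education). Because the ILR basis is
orthonormal, the coordinates are non-collinear and the compositional block
can be tested jointly with a nested-model F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from . import coda
from .coda import IlrBasis
from .errors import (
    ConfigurationError,
    DataFormatError,
    ModelError,
    PreconditionError,
)

DEFAULT_COVARIATES = ("sex", "ethnicity", "fsm", "maternal_education")


def encode_covariates(
    profiles: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    reference: Optional[Mapping[str, str]] = None,
    categories: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Treatment (dummy) coding with the modal category as reference.

    One 0/1 column per non-reference category, named ``covariate=category``,
    in deterministic order (column order of *profiles*, categories sorted).
    *reference* overrides the per-covariate reference; *categories* fixes the
    admissible category sets (values outside them are a data error, which is
    how unseen categories at prediction time surface). A covariate with a
    single observed category contributes no columns (warned).
    """
    if columns is None:
        columns = [c for c in profiles.columns if c != "participant_id"]
    out = {}
    for col in columns:
        if col not in profiles.columns:
            raise DataFormatError(f"covariate column {col!r} not in table")
        if profiles[col].isna().any():
            raise PreconditionError(f"covariate {col!r} has missing values")
        vals = profiles[col].astype(str)
        if categories and col in categories:
            allowed = list(categories[col])
            unseen = set(vals) - set(allowed)
            if unseen:
                raise DataFormatError(
                    f"unseen categories in {col!r}: {sorted(unseen)}"
                )
            cats = sorted(allowed)
        else:
            cats = sorted(vals.unique())
        if reference and col in reference:
            ref = reference[col]
            if ref not in cats:
                raise ConfigurationError(
                    f"reference {ref!r} is not a category of {col!r}"
                )
        else:
            counts = vals.value_counts()
            top = counts.max()
            ref = sorted(counts[counts == top].index)[0]  # modal, ties alphabetical
        non_ref = [c for c in cats if c != ref]
        if not non_ref:
            warnings.warn(f"covariate {col!r} has a single category; dropped")
            continue
        for cat in non_ref:
            out[f"{col}={cat}"] = (vals == cat).astype(float).to_numpy()
    return pd.DataFrame(out, index=profiles.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise :class:`ModelError` naming aliased columns if X is rank-deficient."""
    A = X.to_numpy(dtype=float)
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [X.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise ModelError(f"design matrix is rank-deficient; aliased columns: {aliased}")


@dataclass
class FittedOutcomeModel:
    """OLS fit of the outcome on [1, ILR coordinates, covariate dummies]."""

    params: pd.Series
    cov_params: pd.DataFrame
    residual_df: int
    n: int
    basis: IlrBasis
    ilr_names: list[str]
    dummy_names: list[str]
    outcome_name: str
    reference: dict[str, str]
    categories: dict[str, list[str]]
    rss: float
    results: object = None  # statsmodels results, kept for predictions

    @property
    def beta_ilr(self) -> np.ndarray:
        return self.params[self.ilr_names].to_numpy(dtype=float)

    @property
    def cov_ilr(self) -> np.ndarray:
        return self.cov_params.loc[self.ilr_names, self.ilr_names].to_numpy(dtype=float)

    def design_row(self, composition: pd.Series, covariate_row: Mapping[str, str]) -> pd.Series:
        """Design vector for one composition + covariate profile (for prediction)."""
        z = coda.ilr(composition, self.basis)
        row = {"const": 1.0}
        row.update(dict(zip(self.ilr_names, z)))
        profile = pd.DataFrame([dict(covariate_row)])
        dummies = encode_covariates(
            profile,
            columns=list(self.reference),
            reference=self.reference,
            categories=self.categories,
        )
        for name in self.dummy_names:
            row[name] = float(dummies[name].iloc[0]) if name in dummies.columns else 0.0
        return pd.Series(row)[self.params.index]

    def predict(self, composition: pd.Series, covariate_row: Mapping[str, str]) -> float:
        return float(self.design_row(composition, covariate_row) @ self.params)

    def coefficient_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        return pd.DataFrame(
            {"coefficient": self.params, "se": se}, index=self.params.index
        )


def _design(
    table: pd.DataFrame,
    basis: IlrBasis,
    covariate_names: Sequence[str],
    reference: Optional[Mapping[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], dict[str, list[str]]]:
    parts = list(basis.parts)
    missing = set(parts) - set(table.columns)
    if missing:
        raise DataFormatError(f"analytic table lacks part columns {sorted(missing)}")
    comp = table[parts]
    if (comp.to_numpy(dtype=float) <= 0).any():
        raise PreconditionError(
            "analytic compositions contain zeros; apply multiplicative zero "
            "replacement before fitting"
        )
    z = coda.ilr(comp, basis)
    ilr_names = basis.coordinate_names()
    Z = pd.DataFrame(z, columns=ilr_names, index=table.index)

    ref = dict(reference) if reference else {}
    cats: dict[str, list[str]] = {}
    for col in covariate_names:
        vals = table[col].astype(str)
        cats[col] = sorted(vals.unique())
        if col not in ref:
            counts = vals.value_counts()
            top = counts.max()
            ref[col] = sorted(counts[counts == top].index)[0]
    dummies = encode_covariates(
        table, columns=list(covariate_names), reference=ref, categories=cats
    )
    return Z, dummies, ref, cats


def fit_outcome_model(
    table: pd.DataFrame,
    basis: IlrBasis,
    outcome_name: str = "attainment8",
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    reference: Optional[Mapping[str, str]] = None,
) -> FittedOutcomeModel:
    """Fit OLS of *outcome_name* on ILR coordinates plus covariate dummies.

    The analytic *table* must hold strictly positive part columns matching
    the basis (zero-replaced), the covariate columns and the outcome.
    Coefficient covariance is the classical ``s^2 (X'X)^{-1}``.
    """
    Z, dummies, ref, cats = _design(table, basis, covariate_names, reference)
    X = pd.concat([Z, dummies], axis=1)
    X.insert(0, "const", 1.0)
    y = pd.to_numeric(table[outcome_name], errors="raise")
    n, p = X.shape
    if n <= p:
        raise ModelError(f"need more rows than parameters (n={n}, p={p})")
    _check_full_rank(X)
    res = sm.OLS(y.to_numpy(dtype=float), X).fit()
    return FittedOutcomeModel(
        params=pd.Series(res.params, index=X.columns),
        cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        residual_df=int(res.df_resid),
        n=n,
        basis=basis,
        ilr_names=list(Z.columns),
        dummy_names=list(dummies.columns),
        outcome_name=outcome_name,
        reference=ref,
        categories=cats,
        rss=float(res.ssr),
        results=res,
    )


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float


def joint_composition_test(full: FittedOutcomeModel, table: pd.DataFrame) -> FTestResult:
    """Nested-model F test of the whole ILR block.

    Compares the full model against the covariates-only model on the same
    rows: ``F = ((RSS_r - RSS_f)/df1) / (RSS_f/df2)`` with ``df1 = D-1``.
    """
    df1 = len(full.ilr_names)
    if df1 == 0:
        raise ConfigurationError("full model has no ILR coordinates to test")
    dummies = encode_covariates(
        table,
        columns=list(full.reference),
        reference=full.reference,
        categories=full.categories,
    )
    Xr = dummies.copy()
    Xr.insert(0, "const", 1.0)
    y = pd.to_numeric(table[full.outcome_name], errors="raise").to_numpy(dtype=float)
    res_r = sm.OLS(y, Xr).fit()
    rss_r, rss_f = float(res_r.ssr), full.rss
    df2 = full.residual_df
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    F = max(F, 0.0)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return FTestResult(F=float(F), df1=df1, df2=df2, p=p)


def describe_sample(
    table: pd.DataFrame,
    categorical: Optional[Sequence[str]] = None,
    continuous: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Cohort-characteristics summary: n (%) per category, mean (SD) otherwise.

    Columns are classified by dtype when not given explicitly;
    ``participant_id`` is ignored.
    """
    if table.empty:
        raise PreconditionError("cannot describe an empty table")
    cols = [c for c in table.columns if c != "participant_id"]
    if categorical is None:
        categorical = [c for c in cols if not pd.api.types.is_numeric_dtype(table[c])]
    if continuous is None:
        continuous = [c for c in cols if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    n = len(table)
    for col in categorical:
        counts = table[col].astype(str).value_counts()
        for cat in sorted(counts.index):
            k = int(counts[cat])
            pct = 100.0 * k / n
            rows.append(
                {
                    "variable": col,
                    "level": cat,
                    "n": k,
                    "percent": pct,
                    "mean": np.nan,
                    "sd": np.nan,
                    "formatted": f"{k} ({pct:.1f})",
                }
            )
    for col in continuous:
        vals = pd.to_numeric(table[col], errors="raise")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "variable": col,
                "level": "",
                "n": n,
                "percent": np.nan,
                "mean": mean,
                "sd": sd,
                "formatted": f"{mean:.1f} ({sd:.1f})",
            }
        )
    return pd.DataFrame(rows)


def compare_samples(
    included: pd.DataFrame,
    excluded: pd.DataFrame,
    categorical: Optional[Sequence[str]] = None,
    continuous: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Included-vs-excluded comparison: Welch t-tests and chi-square tests.

    Continuous variables get an unequal-variance (Welch) t-test; categoricals
    a Pearson chi-square on the group x category table without continuity
    correction. Categories absent from both groups are dropped; a variable
    with a single category across both groups is dropped with a warning.
    """
    if included.empty or excluded.empty:
        raise PreconditionError("both samples must be non-empty")
    cols = [c for c in included.columns if c != "participant_id" and c in excluded.columns]
    if categorical is None:
        categorical = [c for c in cols if not pd.api.types.is_numeric_dtype(included[c])]
    if continuous is None:
        continuous = [c for c in cols if pd.api.types.is_numeric_dtype(included[c])]
    rows = []
    for col in continuous:
        a = pd.to_numeric(included[col], errors="coerce").dropna()
        b = pd.to_numeric(excluded[col], errors="coerce").dropna()
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": col,
                "test": "welch_t",
                "statistic": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    for col in categorical:
        a = included[col].astype(str)
        b = excluded[col].astype(str)
        cats = sorted(set(a) | set(b))
        if len(cats) < 2:
            warnings.warn(f"covariate {col!r} has one category in both groups; dropped")
            continue
        counts = np.array(
            [[int((a == c).sum()) for c in cats], [int((b == c).sum()) for c in cats]]
        )
        chi2, p, dof, _ = scipy.stats.chi2_contingency(counts, correction=False)
        rows.append(
            {
                "variable": col,
                "test": "chi2",
                "statistic": float(chi2),
                "df": float(dof),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
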