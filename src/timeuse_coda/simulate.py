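"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes so that the whole
pipeline — diary recoding, validation, zero replacement, ILR regression and
isotemporal substitution — can be exercised end-to-end with recoverable
generating parameters:

* categorical covariates drawn from configurable frequencies,
* daily compositions drawn logistic-normally (Gaussian in ILR space around
  the ILR image of a target geometric-mean profile), inverted to the simplex,
  closed to 1440 min and rounded to the 10-minute diary grid by
  largest-remainder apportionment — so structural zeros arise mechanically
  from the grid, the way diary zeros arise in reality,
* an attainment-like outcome generated linearly from ILR coordinates plus
  covariate dummy effects plus Gaussian noise,
* diary expansion back to 144 coded slots, with optional injected corruption
  (blanked slots, relabelled sleep) to exercise the validity filters.

The composition law is logistic-normal rather than Dirichlet so the
generating model coincides with the analysis model and noiseless recovery is
exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import coda, model
from .coda import MINUTES_PER_DAY, WEEKDAY_PARTS, WEEKEND_PARTS, IlrBasis
from .diary import (
    ActivityMapping,
    N_SLOTS,
    SLOT_MINUTES,
    TimeUseDiary,
)
from .errors import ConfigurationError, PreconditionError

# Covariate category frequencies: modal categories match a typical UK birth
# cohort at age 14 (54.2% female, 79.7% White British, 7.1% FSM-eligible,
# 38.3% degree-educated mothers); the remaining mass is split plausibly.
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.542, "male": 0.458},
    "ethnicity": {
        "white_british": 0.797,
        "mixed": 0.050,
        "indian": 0.030,
        "pakistani_bangladeshi": 0.060,
        "black": 0.030,
        "other": 0.033,
    },
    "fsm": {"no": 0.929, "yes": 0.071},
    "maternal_education": {
        "none": 0.050,
        "overseas": 0.030,
        "nvq1": 0.080,
        "nvq2": 0.250,
        "nvq3": 0.207,
        "nvq4": 0.383,
    },
}

# Geometric-mean day profiles (minutes, summing to 1440): weekday six-part
# and weekend four-part targets for a mid-adolescent cohort.
WEEKDAY_GEOMETRIC_MEAN: dict[str, float] = {
    "sleep": 897.0,
    "physical_activity": 23.0,
    "media": 143.0,
    "school": 50.0,
    "hobbies": 61.0,
    "domestic": 266.0,
}
WEEKEND_GEOMETRIC_MEAN: dict[str, float] = {
    "sleep": 852.0,
    "media": 202.0,
    "hobbies": 114.0,
    "domestic": 272.0,
}

# Default covariate effects on the outcome (attainment points, relative to
# the modal reference category of each covariate).
DEFAULT_BETA_COV: dict[str, float] = {
    "sex=male": -1.5,
    "fsm=yes": -8.0,
    "ethnicity=mixed": -1.0,
    "ethnicity=indian": 3.0,
    "ethnicity=pakistani_bangladeshi": -2.0,
    "ethnicity=black": -1.0,
    "ethnicity=other": 0.5,
    "maternal_education=none": -10.0,
    "maternal_education=overseas": -6.0,
    "maternal_education=nvq1": -8.0,
    "maternal_education=nvq2": -5.0,
    "maternal_education=nvq3": -3.0,
}

DEFAULT_BETA_ILR_WEEKDAY = (-4.0, 3.0, 1.0, -1.5, 0.5)
DEFAULT_BETA_ILR_WEEKEND = (-3.0, 1.0, 1.5)

# Per-coordinate ILR standard deviations for the weekday pivot order
# (sleep, PA, media, school, hobbies, domestic): sleep-vs-rest varies little
# between adolescents, scarce behaviours (PA, school out of school hours)
# vary a lot on the log scale.
DEFAULT_ILR_SD_WEEKDAY = (0.15, 0.80, 0.60, 0.70, 0.70)
DEFAULT_ILR_SD_WEEKEND = (0.15, 0.60, 0.70)


def _diag_scale(sds: Sequence[float]) -> np.ndarray:
    return np.diag(np.square(np.asarray(sds, dtype=float)))


@dataclass
class SyntheticTruth:
    """Generating parameters for a synthetic cohort, with invariants checked.

    ``target_geometric_mean`` maps behaviour sets to minutes (must sum to
    1440); ``ilr_scale`` is the (D-1)x(D-1) covariance of the Gaussian ILR
    draws; ``beta_ilr`` are outcome coefficients on the ILR coordinates of
    the default pivot basis; ``beta_cov`` maps dummy-column names
    (``covariate=category``) to effects; ``zero_resolution`` is the diary
    grid in minutes; ``missing_slot_rate`` / ``zero_sleep_rate`` inject
    diary corruption.
    """

    target_geometric_mean: dict[str, float] = field(
        default_factory=lambda: dict(WEEKDAY_GEOMETRIC_MEAN)
    )
    ilr_scale: np.ndarray = field(
        default_factory=lambda: _diag_scale(DEFAULT_ILR_SD_WEEKDAY)
    )
    beta_ilr: tuple[float, ...] = DEFAULT_BETA_ILR_WEEKDAY
    beta_cov: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_COV))
    intercept: float = 60.0
    noise_sd: float = 13.0
    covariate_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_FREQS.items()}
    )
    zero_resolution: int = SLOT_MINUTES
    missing_slot_rate: float = 0.0
    zero_sleep_rate: float = 0.0
    clip_outcome: bool = False
    seed: int = 0

    def __post_init__(self):
        gm = np.asarray(list(self.target_geometric_mean.values()), dtype=float)
        if np.any(gm <= 0):
            raise ConfigurationError("target_geometric_mean parts must be positive")
        if abs(gm.sum() - MINUTES_PER_DAY) > 1e-6:
            raise ConfigurationError(
                f"target_geometric_mean must sum to {MINUTES_PER_DAY}, got {gm.sum()}"
            )
        D = len(gm)
        S = np.asarray(self.ilr_scale, dtype=float)
        if S.shape != (D - 1, D - 1):
            raise ConfigurationError(f"ilr_scale must be {(D - 1, D - 1)}, got {S.shape}")
        if np.max(np.abs(S - S.T)) > 1e-10:
            raise ConfigurationError("ilr_scale must be symmetric")
        if np.min(np.linalg.eigvalsh(S)) < -1e-10:
            raise ConfigurationError("ilr_scale must be positive semi-definite")
        self.ilr_scale = S
        if len(self.beta_ilr) != D - 1:
            raise ConfigurationError(f"beta_ilr must have {D - 1} entries")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for rate_name in ("missing_slot_rate", "zero_sleep_rate"):
            r = getattr(self, rate_name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{rate_name} must lie in [0, 1], got {r}")
        for cov_name, freqs in self.covariate_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"covariate_freqs[{cov_name!r}] must sum to 1, got {tot}"
                )
            if any(p < 0 for p in freqs.values()):
                raise ConfigurationError(f"negative probability in {cov_name!r}")

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.target_geometric_mean)

    @property
    def n_parts(self) -> int:
        return len(self.target_geometric_mean)

    def basis(self) -> IlrBasis:
        return coda.make_pivot_basis(self.parts)

    def reference_categories(self) -> dict[str, str]:
        """Modal category per covariate under the generating frequencies."""
        return {
            cov: max(sorted(freqs), key=lambda c: freqs[c])
            for cov, freqs in self.covariate_freqs.items()
        }

    def to_json(self, path) -> None:
        d = asdict(self)
        d["ilr_scale"] = np.asarray(self.ilr_scale).tolist()
        d["beta_ilr"] = list(self.beta_ilr)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @staticmethod
    def from_dict(d: Mapping) -> "SyntheticTruth":
        d = dict(d)
        if "ilr_scale" in d:
            d["ilr_scale"] = np.asarray(d["ilr_scale"], dtype=float)
        if "beta_ilr" in d:
            d["beta_ilr"] = tuple(d["beta_ilr"])
        return SyntheticTruth(**d)


def weekday_truth(**overrides) -> SyntheticTruth:
    """Default six-part weekday generating process."""
    return SyntheticTruth(**overrides)


def weekend_truth(**overrides) -> SyntheticTruth:
    """Default four-part weekend generating process (no PA / school sets)."""
    defaults = dict(
        target_geometric_mean=dict(WEEKEND_GEOMETRIC_MEAN),
        ilr_scale=_diag_scale(DEFAULT_ILR_SD_WEEKEND),
        beta_ilr=DEFAULT_BETA_ILR_WEEKEND,
    )
    defaults.update(overrides)
    return SyntheticTruth(**defaults)


def _rng(truth: SyntheticTruth, salt: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([truth.seed, salt])


def generate_covariates(truth: SyntheticTruth, n: int) -> pd.DataFrame:
    """Draw *n* independent covariate profiles from the configured frequencies."""
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    rng = _rng(truth, 1)
    cols = {}
    for cov_name, freqs in truth.covariate_freqs.items():
        cats = list(freqs)
        probs = np.array([freqs[c] for c in cats], dtype=float)
        cols[cov_name] = rng.choice(cats, size=n, p=probs / probs.sum())
    return pd.DataFrame(cols)


def round_to_grid(
    values, resolution: int = SLOT_MINUTES, total: float = MINUTES_PER_DAY
) -> np.ndarray:
    """Round compositions to the diary grid by largest-remainder apportionment.

    Each row of *values* (closed to *total*) is expressed in grid units,
    floored, and the leftover units are given to the parts with the largest
    fractional remainders — ties broken by part order — so every rounded row
    still sums to *total* exactly. Parts may round to exactly zero.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n_units = total / resolution
    if abs(n_units - round(n_units)) > 1e-9:
        raise ConfigurationError("total must be a multiple of the grid resolution")
    n_units = int(round(n_units))
    q = v / resolution
    fl = np.floor(q)
    rem = q - fl
    deficit = np.rint(n_units - fl.sum(axis=1)).astype(int)
    # stable argsort of -remainder ranks parts by remainder, ties by index
    order = np.argsort(-rem, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(v.shape[0])[:, None]
    ranks[rows, order] = np.arange(v.shape[1])[None, :]
    add = (ranks < deficit[:, None]).astype(float)
    out = (fl + add) * resolution
    return out if np.asarray(values).ndim > 1 else out[0]


def generate_compositions(truth: SyntheticTruth, n: int) -> pd.DataFrame:
    """Draw *n* daily compositions on the 10-minute grid (minutes, sum 1440).

    ILR vectors are drawn from a Gaussian centred at the ILR image of the
    target geometric mean, inverted to the simplex, closed to 1440 and
    rounded to the grid; zeros can arise from the rounding.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    basis = truth.basis()
    rng = _rng(truth, 2)
    centre = coda.ilr(pd.Series(truth.target_geometric_mean), basis)
    z = rng.multivariate_normal(centre, truth.ilr_scale, size=n, method="svd")
    cont = coda.ilr_inverse(z, basis)
    grid = round_to_grid(cont.to_numpy(), resolution=truth.zero_resolution)
    return pd.DataFrame(grid, columns=list(truth.parts))


def generate_outcome(
    compositions: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    basis: Optional[IlrBasis] = None,
) -> pd.Series:
    """Generate the attainment outcome from ILR coordinates + covariates.

    ``y_i = intercept + ilr(x_i) . beta_ilr + dummies_i . beta_cov + eps_i``
    with ``eps_i ~ N(0, noise_sd^2)``. Compositions must be strictly positive
    (apply :func:`coda.multiplicative_zero_replace` first). Clipping to the
    attainment range [0, 90] is off by default because it breaks the
    linearity that parameter-recovery checks rely on; when enabled it is
    flagged with a warning.
    """
    basis = basis or truth.basis()
    if len(compositions) != len(covariates):
        raise PreconditionError("compositions and covariates must have equal rows")
    vals = compositions.loc[:, list(basis.parts)].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise PreconditionError(
            "compositions contain zeros; apply multiplicative zero replacement "
            "before generating outcomes"
        )
    z = np.log(vals) @ basis.V
    y = truth.intercept + z @ np.asarray(truth.beta_ilr, dtype=float)
    dummies = model.encode_covariates(
        covariates,
        reference=truth.reference_categories(),
        categories={c: sorted(f) for c, f in truth.covariate_freqs.items()},
    )
    for col in dummies.columns:
        y = y + dummies[col].to_numpy(dtype=float) * truth.beta_cov.get(col, 0.0)
    rng = _rng(truth, 3)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    if truth.clip_outcome:
        import warnings

        warnings.warn("clipping outcomes to [0, 90]; linearity no longer holds")
        y = np.clip(y, 0.0, 90.0)
    return pd.Series(y, index=compositions.index, name="attainment8")


def expand_to_diary(
    composition: pd.Series,
    truth: SyntheticTruth,
    mapping: Optional[ActivityMapping] = None,
    participant_id: str = "p0",
    day_type: str = "weekday",
    rng: Optional[np.random.Generator] = None,
) -> TimeUseDiary:
    """Expand a grid composition into a 144-slot diary.

    Sleep is anchored at the start and end of the 04:00-04:00 window (the
    tail of the previous night, then the start of the next); the other sets
    fill the middle as contiguous blocks in randomised order. With
    probability ``missing_slot_rate`` each slot is blanked, and with
    probability ``zero_sleep_rate`` all sleep slots are relabelled to the
    domestic set, producing diaries the validity filters must reject.
    """
    mapping = mapping or ActivityMapping.default()
    rng = rng if rng is not None else _rng(truth, 4)
    mins = composition.astype(float)
    if np.any(np.mod(mins.to_numpy(), SLOT_MINUTES) != 0):
        raise PreconditionError("composition parts must be multiples of 10 minutes")
    if abs(mins.sum() - MINUTES_PER_DAY) > 1e-9:
        raise PreconditionError("composition must sum to 1440 minutes")
    code_for = {s: mapping.codes_for(s)[0] for s in mins.index}
    slot_counts = {s: int(m) // SLOT_MINUTES for s, m in mins.items()}

    n_sleep = slot_counts.get("sleep", 0)
    tail = n_sleep // 2  # previous night's sleep ends the 4am-4am window
    head = n_sleep - tail
    others = [s for s in mins.index if s != "sleep" and slot_counts[s] > 0]
    order = list(rng.permutation(others)) if others else []

    slots: list[Optional[str]] = []
    slots += [code_for["sleep"]] * head
    for s in order:
        slots += [code_for[s]] * slot_counts[s]
    slots += [code_for["sleep"]] * tail
    assert len(slots) == N_SLOTS

    if truth.zero_sleep_rate > 0 and rng.random() < truth.zero_sleep_rate:
        dom = mapping.codes_for("domestic")[0]
        sleep_codes = set(mapping.codes_for("sleep"))
        slots = [dom if s in sleep_codes else s for s in slots]
    if truth.missing_slot_rate > 0:
        blank = rng.random(N_SLOTS) < truth.missing_slot_rate
        slots = [None if b else s for s, b in zip(slots, blank)]
    return TimeUseDiary(participant_id=participant_id, day_type=day_type, slots=slots)


@dataclass
class SyntheticCohort:
    """A generated cohort: tables ready for the pipeline, plus ground truth."""

    truth: SyntheticTruth
    day_type: str
    covariates: pd.DataFrame  # participant_id + covariate columns
    compositions: pd.DataFrame  # participant_id + part columns (grid minutes)
    outcomes: pd.DataFrame  # participant_id, attainment8, passes
    diaries: list[TimeUseDiary]

    def diary_table(self) -> pd.DataFrame:
        """Long-format diary rows; MISSING slots are omitted (absent rows)."""
        recs = []
        for d in self.diaries:
            for idx, code in enumerate(d.slots):
                if code is not None:
                    recs.append(
                        {
                            "participant_id": d.participant_id,
                            "day_type": d.day_type,
                            "slot_index": idx,
                            "activity_code": code,
                        }
                    )
        return pd.DataFrame(recs)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diary_table().to_csv(out / "diaries.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.compositions.to_csv(out / "compositions.csv", index=False)
        self.truth.to_json(out / "truth.json")


def generate_cohort(
    truth: SyntheticTruth,
    n: int,
    day_type: str = "weekday",
    mapping: Optional[ActivityMapping] = None,
    impute: float = 5.0,
) -> SyntheticCohort:
    """Generate a full cohort: covariates, compositions, outcomes, diaries.

    Outcomes are generated from the zero-replaced compositions (the same
    imputation the analysis applies), so the analysis model is exactly the
    generating model. Weekend cohorts use four-part compositions; their
    diaries simply contain no PA/school slots.
    """
    mapping = mapping or ActivityMapping.default()
    if day_type not in ("weekday", "weekend"):
        raise ConfigurationError(f"day_type must be weekday or weekend, got {day_type!r}")
    expected = WEEKDAY_PARTS if day_type == "weekday" else WEEKEND_PARTS
    if truth.parts != tuple(expected):
        raise ConfigurationError(
            f"truth parts {truth.parts} do not match {day_type} sets {expected}"
        )
    ids = [f"p{i + 1:05d}" for i in range(n)]
    covs = generate_covariates(truth, n)
    comps = generate_compositions(truth, n)
    replaced = coda.multiplicative_zero_replace(comps, impute=impute)
    y = generate_outcome(replaced, covs, truth, truth.basis())
    passes = np.clip(np.rint(y * 10.0 / 90.0), 0, 10).astype(int)

    diary_rng = _rng(truth, 4)
    diaries = [
        expand_to_diary(
            comps.iloc[i],
            truth,
            mapping,
            participant_id=ids[i],
            day_type=day_type,
            rng=diary_rng,
        )
        for i in range(n)
    ]
    covariates = covs.copy()
    covariates.insert(0, "participant_id", ids)
    compositions = comps.copy()
    compositions.insert(0, "participant_id", ids)
    outcomes = pd.DataFrame(
        {"participant_id": ids, "attainment8": y.to_numpy(), "passes": passes}
    )
    return SyntheticCohort(
        truth=truth,
        day_type=day_type,
        covariates=covariates,
        compositions=compositions,
        outcomes=outcomes,
        diaries=diaries,
    )


def inject_corruption(
    cohort: SyntheticCohort,
    n_missing_covariate: int = 0,
    n_missing_slots: int = 0,
    n_no_sleep: int = 0,
    n_missing_outcome: int = 0,
    mapping: Optional[ActivityMapping] = None,
) -> tuple[SyntheticCohort, dict[str, int]]:
    """Corrupt disjoint blocks of participants to exercise every filter.

    The first ``n_missing_covariate`` participants lose a covariate value,
    the next ``n_missing_slots`` get one diary slot blanked, the next
    ``n_no_sleep`` have all sleep slots relabelled to domestic, and the next
    ``n_missing_outcome`` lose their outcome. Because the blocks are
    disjoint, the complete-case filters remove exactly these counts in
    order; the expected removal counts per step are returned alongside the
    corrupted cohort.
    """
    mapping = mapping or ActivityMapping.default()
    total = n_missing_covariate + n_missing_slots + n_no_sleep + n_missing_outcome
    if total > len(cohort.covariates):
        raise ConfigurationError("more corruption requested than participants")
    covs = cohort.covariates.copy()
    outs = cohort.outcomes.copy()
    diaries = [
        TimeUseDiary(d.participant_id, d.day_type, list(d.slots))
        for d in cohort.diaries
    ]
    i = 0
    covs.loc[covs.index[i : i + n_missing_covariate], "sex"] = np.nan
    i += n_missing_covariate
    for d in diaries[i : i + n_missing_slots]:
        d.slots[10] = None
    i += n_missing_slots
    sleep_codes = set(mapping.codes_for("sleep"))
    dom = mapping.codes_for("domestic")[0]
    for d in diaries[i : i + n_no_sleep]:
        d.slots = [dom if s in sleep_codes else s for s in d.slots]
    i += n_no_sleep
    outs.loc[outs.index[i : i + n_missing_outcome], ["attainment8", "passes"]] = np.nan
    expected = {
        "covariates": n_missing_covariate,
        "diary_validity": n_missing_slots + n_no_sleep,
        "outcome": n_missing_outcome,
    }
    corrupted = SyntheticCohort(
        truth=cohort.truth,
        day_type=cohort.day_type,
        covariates=covs,
        compositions=cohort.compositions,
        outcomes=outs,
        diaries=diaries,
    )
    return corrupted, expected
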