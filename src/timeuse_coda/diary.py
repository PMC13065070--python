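"""Time-use diary parsing, recoding, validation and analytic-sample assembly.

A diary covers one person-day as 144 ten-minute slots running from 04:00 to
04:00 the next day (slot ``k`` covers the half-open interval
``[04:00 + 10k, 04:00 + 10(k+1))``, 0-based). Each slot holds one activity
code from a configurable vocabulary; codes are recoded into mutually
exclusive behaviour sets (six on weekdays, four at weekends) whose minutes
sum to 1440.

Diaries with any unfilled slot, or with no sleep or no domestic/personal-care
time at all, are treated as unreliable accounts of a complete day and
excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import coda
from .coda import WEEKDAY_PARTS, WEEKEND_PARTS
from .errors import (
    ConfigurationError,
    DataFormatError,
    PipelineError,
    PreconditionError,
)

N_SLOTS = 144
SLOT_MINUTES = 10
MISSING = None  # sentinel for an unfilled slot

DAY_TYPES = ("weekday", "weekend")

#: Default activity-code vocabulary: plausible codes for the 12 diary
#: categories, assigned to the six behaviour sets. Real studies define this
#: mapping from their instrument's codebook; it is fully overridable via a
#: mapping CSV (columns: activity_code, behaviour_set).
DEFAULT_MAPPING_ENTRIES: dict[str, str] = {
    "sleep": "sleep",
    "nap": "sleep",
    "sports": "physical_activity",
    "exercise": "physical_activity",
    "active_travel": "physical_activity",
    "tv": "media",
    "video_games": "media",
    "internet": "media",
    "social_media": "media",
    "school_lessons": "school",
    "homework": "school",
    "reading": "hobbies",
    "music": "hobbies",
    "socialising": "hobbies",
    "arts_crafts": "hobbies",
    "personal_care": "domestic",
    "eating": "domestic",
    "chores": "domestic",
    "paid_work": "domestic",
    "travel": "domestic",
}


@dataclass(frozen=True)
class ActivityMapping:
    """Total mapping from activity codes to behaviour-set names."""

    entries: Mapping[str, str]

    def __post_init__(self):
        bad = {c: s for c, s in self.entries.items() if s not in WEEKDAY_PARTS}
        if bad:
            raise ConfigurationError(
                f"mapping assigns codes to unknown behaviour sets: {bad}"
            )
        mapped = set(self.entries.values())
        missing = set(WEEKDAY_PARTS) - mapped
        if missing:
            raise ConfigurationError(
                f"mapping has no activity codes for behaviour sets {sorted(missing)}"
            )

    @staticmethod
    def default() -> "ActivityMapping":
        return ActivityMapping(dict(DEFAULT_MAPPING_ENTRIES))

    @staticmethod
    def from_csv(path) -> "ActivityMapping":
        df = pd.read_csv(path, dtype=str)
        required = {"activity_code", "behaviour_set"}
        if not required.issubset(df.columns):
            raise DataFormatError(f"mapping CSV needs columns {sorted(required)}")
        dup = df["activity_code"][df["activity_code"].duplicated()]
        if not dup.empty:
            raise DataFormatError(
                f"activity codes mapped more than once: {sorted(dup.unique())}"
            )
        return ActivityMapping(dict(zip(df["activity_code"], df["behaviour_set"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"activity_code": list(self.entries), "behaviour_set": list(self.entries.values())}
        ).to_csv(path, index=False)

    def behaviour_sets(self, day_type: str) -> tuple[str, ...]:
        """Ordered part names for the given day type."""
        if day_type == "weekday":
            return WEEKDAY_PARTS
        if day_type == "weekend":
            return WEEKEND_PARTS
        raise ConfigurationError(f"day_type must be one of {DAY_TYPES}, got {day_type!r}")

    def set_of(self, code: str) -> str:
        try:
            return self.entries[code]
        except KeyError:
            raise DataFormatError(f"unknown activity code {code!r}") from None

    def codes_for(self, behaviour_set: str) -> list[str]:
        return sorted(c for c, s in self.entries.items() if s == behaviour_set)


@dataclass
class TimeUseDiary:
    """One person-day: 144 coded 10-minute slots starting 04:00."""

    participant_id: str
    day_type: str
    slots: list[Optional[str]]

    def __post_init__(self):
        if self.day_type not in DAY_TYPES:
            raise DataFormatError(
                f"day_type must be one of {DAY_TYPES}, got {self.day_type!r}"
            )
        if len(self.slots) != N_SLOTS:
            raise DataFormatError(
                f"a diary needs exactly {N_SLOTS} slots, got {len(self.slots)}"
            )

    @property
    def n_missing(self) -> int:
        return sum(s is MISSING for s in self.slots)


class InvalidReason(str, Enum):
    NONE = "none"
    MISSING_DATA = "missing_data"
    NO_SLEEP = "no_sleep"
    NO_DOMESTIC = "no_domestic"


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reason: InvalidReason

    def __post_init__(self):
        if self.valid != (self.reason is InvalidReason.NONE):
            raise ValueError("reason must be 'none' iff valid")


def parse_diary_table(path_or_df, mapping: ActivityMapping) -> list[TimeUseDiary]:
    """Read a long-format diary CSV into diaries, one per (participant, day type).

    Expected columns: ``participant_id``, ``day_type``, ``slot_index`` (0-143)
    and ``activity_code``. Slots absent from the table become MISSING;
    duplicate (participant, day_type, slot) rows, out-of-range slot indices
    and unknown activity codes are format errors.
    """
    if isinstance(path_or_df, (str, Path)):
        df = pd.read_csv(path_or_df, dtype={"participant_id": str, "activity_code": str})
    else:
        df = path_or_df.copy()
        df["participant_id"] = df["participant_id"].astype(str)
    required = {"participant_id", "day_type", "slot_index", "activity_code"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"diary table needs columns {sorted(required)}")
    slots = pd.to_numeric(df["slot_index"], errors="raise").astype(int)
    bad = slots[(slots < 0) | (slots >= N_SLOTS)]
    if not bad.empty:
        raise DataFormatError(
            f"slot_index must lie in 0..{N_SLOTS - 1}; found {sorted(bad.unique())}"
        )
    df = df.assign(slot_index=slots)
    dup = df.duplicated(subset=["participant_id", "day_type", "slot_index"])
    if dup.any():
        rows = df.loc[dup, ["participant_id", "day_type", "slot_index"]]
        raise DataFormatError(
            f"duplicate diary slot rows (participant, day_type, slot): "
            f"{rows.head().to_dict('records')}"
        )
    unknown = set(df["activity_code"].dropna()) - set(mapping.entries)
    if unknown:
        raise DataFormatError(f"unknown activity codes: {sorted(unknown)}")

    diaries = []
    for (pid, day_type), grp in df.groupby(["participant_id", "day_type"], sort=True):
        filled: list[Optional[str]] = [MISSING] * N_SLOTS
        for idx, code in zip(grp["slot_index"], grp["activity_code"]):
            filled[idx] = None if pd.isna(code) else code
        diaries.append(TimeUseDiary(participant_id=pid, day_type=day_type, slots=filled))
    return diaries


def recode_diary(diary: TimeUseDiary, mapping: ActivityMapping) -> pd.Series:
    """Recode a complete diary into minutes per behaviour set.

    Minutes per set = 10 x slot count, so the parts always sum to 1440.
    Counting is always into the six weekday sets; for weekend analyses the
    four-part subcomposition is taken downstream (see
    :func:`build_analytic_sample`).
    """
    if diary.n_missing:
        raise PreconditionError(
            f"diary {diary.participant_id}/{diary.day_type} has "
            f"{diary.n_missing} MISSING slots; validate before recoding"
        )
    counts = {part: 0 for part in WEEKDAY_PARTS}
    for code in diary.slots:
        counts[mapping.set_of(code)] += 1
    return pd.Series(
        {part: counts[part] * SLOT_MINUTES for part in WEEKDAY_PARTS},
        name=diary.participant_id,
        dtype=float,
    )


def validate_diary(diary: TimeUseDiary, mapping: ActivityMapping) -> ValidationResult:
    """Check that a diary is a plausibly complete account of a day.

    Reasons are checked in fixed priority order: any MISSING slot ->
    ``missing_data``; else no sleep slot -> ``no_sleep``; else no
    domestic/personal-care slot -> ``no_domestic``; else valid.
    """
    if diary.n_missing:
        return ValidationResult(False, InvalidReason.MISSING_DATA)
    sets = [mapping.set_of(code) for code in diary.slots]
    if "sleep" not in sets:
        return ValidationResult(False, InvalidReason.NO_SLEEP)
    if "domestic" not in sets:
        return ValidationResult(False, InvalidReason.NO_DOMESTIC)
    return ValidationResult(True, InvalidReason.NONE)


def build_analytic_sample(
    diaries: Iterable[TimeUseDiary],
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    day_type: str,
    mapping: ActivityMapping | None = None,
    outcome_name: str = "attainment8",
    covariate_names: Sequence[str] = ("sex", "ethnicity", "fsm", "maternal_education"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the complete-case analytic table for one day type.

    Starting from participants holding a diary of *day_type*, exclusions are
    applied in fixed order — missing covariates, then invalid diaries
    (missing slots / no sleep / no domestic), then missing outcome — and the
    count removed at each step is logged. Surviving diaries are recoded to
    compositions; weekend compositions are reduced to the four weekend sets
    by subcomposition and re-closed to 1440 min.

    *covariates* and *outcomes* must carry a ``participant_id`` column.
    Returns ``(analytic_table, removal_log)``; raises
    :class:`PipelineError` if nothing survives.
    """
    mapping = mapping or ActivityMapping.default()
    parts = mapping.behaviour_sets(day_type)
    by_pid = {d.participant_id: d for d in diaries if d.day_type == day_type}
    pids = sorted(by_pid)

    cov = covariates.set_index(covariates["participant_id"].astype(str))
    out = outcomes.set_index(outcomes["participant_id"].astype(str))
    log_rows = []

    def _log(step, before, kept, detail=""):
        log_rows.append(
            {
                "step": step,
                "n_before": len(before),
                "n_removed": len(before) - len(kept),
                "n_after": len(kept),
                "detail": detail,
            }
        )

    # 1. complete covariates
    def _covariates_ok(pid):
        if pid not in cov.index:
            return False
        row = cov.loc[pid, list(covariate_names)]
        return not row.isna().any()

    kept = [p for p in pids if _covariates_ok(p)]
    _log("covariates", pids, kept)

    # 2. valid diary
    reasons: dict[str, int] = {}
    valid = []
    for pid in kept:
        res = validate_diary(by_pid[pid], mapping)
        if res.valid:
            valid.append(pid)
        else:
            reasons[res.reason.value] = reasons.get(res.reason.value, 0) + 1
    _log(
        "diary_validity",
        kept,
        valid,
        "; ".join(f"{k}={v}" for k, v in sorted(reasons.items())),
    )

    # 3. non-missing outcome
    def _outcome_ok(pid):
        return pid in out.index and pd.notna(out.loc[pid, outcome_name])

    final = [p for p in valid if _outcome_ok(p)]
    _log("outcome", valid, final)

    removal_log = pd.DataFrame(log_rows)
    if not final:
        raise PipelineError(
            f"no participants survive the {day_type} filters; "
            f"removal log: {removal_log.to_dict('records')}"
        )

    comps = pd.DataFrame(
        [recode_diary(by_pid[pid], mapping) for pid in final], index=final
    )
    if day_type == "weekend":
        comps = coda.subcomposition(comps, list(parts))
    table = pd.concat(
        [
            comps,
            cov.loc[final, list(covariate_names)],
            out.loc[final, [outcome_name]],
        ],
        axis=1,
    )
    table.insert(0, "participant_id", final)
    table = table.reset_index(drop=True)
    return table, removal_log
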