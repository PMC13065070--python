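"""End-to-end pipeline orchestration and table rendering.

``run_pipeline`` drives the full analysis from a config: parse diaries ->
validate & assemble the complete-case sample -> multiplicative zero
replacement -> descriptive tables -> ILR regression -> joint F test ->
pairwise substitution table -> substitution grid, writing deterministic CSV
outputs (stable row order, fixed float formatting) plus a removal log that
accounts for every excluded participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coda, diary as diary_mod, model as model_mod, substitution as subst_mod
from .coda import IlrBasis
from .diary import ActivityMapping
from .errors import ConfigurationError, PipelineError

FLOAT_FMT = "%.10g"

DEFAULT_DELTA = {"weekday": 20.0, "weekend": 30.0}
DEFAULT_GRID_MAX = {"weekday": 20.0, "weekend": 30.0}


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; validated before any compute."""

    diaries: str
    covariates: str
    outcomes: str
    out_dir: str
    mapping: Optional[str] = None
    day_type: str = "weekday"
    impute_minutes: float = 5.0
    delta: Optional[float] = None  # default 20 (weekday) / 30 (weekend)
    grid_max: Optional[float] = None
    grid_step: float = 5.0
    outcome_name: str = "attainment8"
    pivot_order: Optional[Sequence[str]] = None
    base_composition: Optional[dict] = None  # default: sample compositional mean
    seed: int = 0

    def __post_init__(self):
        if self.day_type not in ("weekday", "weekend"):
            raise ConfigurationError(f"day_type must be weekday or weekend, got {self.day_type!r}")
        if not (0 < self.impute_minutes < 10):
            raise ConfigurationError("impute_minutes must lie in (0, 10)")
        if self.delta is None:
            self.delta = DEFAULT_DELTA[self.day_type]
        if self.grid_max is None:
            self.grid_max = DEFAULT_GRID_MAX[self.day_type]
        if self.delta <= 0 or self.grid_max <= 0 or self.grid_step <= 0:
            raise ConfigurationError("delta, grid_max and grid_step must be positive")
        if self.outcome_name not in ("attainment8", "passes"):
            raise ConfigurationError("outcome_name must be 'attainment8' or 'passes'")
        for name in ("diaries", "covariates", "outcomes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} file not found: {p}")
        if self.mapping is not None and not Path(self.mapping).exists():
            raise ConfigurationError(f"mapping file not found: {self.mapping}")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def time_use_table(
    raw_compositions: pd.DataFrame, replaced: pd.DataFrame
) -> pd.DataFrame:
    """Descriptive time-use table: raw mean (SD) and adjusted geometric mean.

    Raw statistics are computed on the recoded minutes including zeros; the
    geometric-mean column is the compositional mean of the zero-replaced
    sample, re-closed to 1440, with the rounded percent of day.
    """
    gm = coda.compositional_mean(replaced)
    pct = coda.part_percentages(gm)
    return pd.DataFrame(
        {
            "behaviour_set": raw_compositions.columns,
            "raw_mean": raw_compositions.mean().to_numpy(),
            "raw_sd": raw_compositions.std(ddof=1).to_numpy(),
            "geometric_mean": gm.to_numpy(),
            "percent_of_day": pct.to_numpy(),
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes CSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    @_stage("load_mapping")
    def _load_mapping():
        if config.mapping is None:
            return ActivityMapping.default()
        return ActivityMapping.from_csv(config.mapping)

    mapping = _load_mapping()

    @_stage("parse_diaries")
    def _parse():
        return diary_mod.parse_diary_table(config.diaries, mapping)

    diaries = _parse()

    @_stage("load_tables")
    def _load_tables():
        cov = pd.read_csv(config.covariates, dtype={"participant_id": str})
        out = pd.read_csv(config.outcomes, dtype={"participant_id": str})
        return cov, out

    covariates, outcomes = _load_tables()

    @_stage("build_sample")
    def _build():
        return diary_mod.build_analytic_sample(
            diaries,
            covariates,
            outcomes,
            day_type=config.day_type,
            mapping=mapping,
            outcome_name=config.outcome_name,
        )

    table, removal_log = _build()
    parts = list(mapping.behaviour_sets(config.day_type))

    @_stage("zero_replacement")
    def _replace():
        raw = table[parts].astype(float)
        return raw, coda.multiplicative_zero_replace(raw, impute=config.impute_minutes)

    raw_comps, replaced = _replace()
    analytic = table.copy()
    analytic[parts] = replaced

    @_stage("describe")
    def _describe():
        desc = model_mod.describe_sample(
            table, categorical=list(model_mod.DEFAULT_COVARIATES),
            continuous=[config.outcome_name],
        )
        tu = time_use_table(raw_comps, replaced)
        return desc, tu

    description, tu_table = _describe()

    @_stage("fit_model")
    def _fit():
        basis = coda.make_pivot_basis(parts, pivot_order=config.pivot_order)
        return model_mod.fit_outcome_model(
            analytic, basis, outcome_name=config.outcome_name
        )

    fitted = _fit()

    @_stage("joint_test")
    def _joint():
        return model_mod.joint_composition_test(fitted, analytic)

    ftest = _joint()

    @_stage("substitutions")
    def _subst():
        if config.base_composition is not None:
            base = coda.closure(pd.Series(config.base_composition, dtype=float))
        else:
            base = coda.compositional_mean(replaced)
        pairwise = subst_mod.pairwise_table(fitted, base, config.delta)
        grid = subst_mod.substitution_grid(
            fitted, base, config.grid_max, config.grid_step
        )
        return base, pairwise, grid

    base, pairwise, grid = _subst()

    bundle = {
        "config": config,
        "mapping": mapping,
        "analytic_table": analytic,
        "raw_compositions": raw_comps,
        "removal_log": removal_log,
        "description": description,
        "time_use_table": tu_table,
        "model": fitted,
        "joint_test": ftest,
        "base_composition": base,
        "pairwise": pairwise,
        "grid": grid,
    }

    @_stage("write_outputs")
    def _write():
        _write_csv(removal_log, out_dir / "removal_log.csv")
        _write_csv(description, out_dir / "sample_characteristics.csv")
        _write_csv(tu_table, out_dir / "time_use_composition.csv")
        _write_csv(fitted.coefficient_table().reset_index(names="term"),
                   out_dir / "model_coefficients.csv")
        _write_csv(fitted.basis.to_frame().reset_index(names="part"),
                   out_dir / "ilr_basis.csv")
        _write_csv(pairwise, out_dir / "substitutions_pairwise.csv")
        _write_csv(grid, out_dir / "substitution_grid.csv")
        _write_csv(analytic, out_dir / "analytic_sample.csv")
        for name, frame in render_tables(bundle).items():
            _write_csv(frame, out_dir / f"{name}.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(
                {
                    "day_type": config.day_type,
                    "outcome": config.outcome_name,
                    "n": fitted.n,
                    "n_parts": len(parts),
                    "n_ilr_coordinates": len(fitted.ilr_names),
                    "joint_F": ftest.F,
                    "joint_df1": ftest.df1,
                    "joint_df2": ftest.df2,
                    "joint_p": ftest.p,
                    "impute_minutes": config.impute_minutes,
                    "delta": config.delta,
                    "seed": config.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    _write()
    return bundle


def _write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def render_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Publication-style formatted tables (2 dp betas, n (%) counts).

    ``time_use_formatted``: raw mean (SD) alongside the adjusted geometric
    mean per behaviour set. ``substitutions_formatted``: beta and 95% CI at
    two decimals, with the significance flag (CI excluding zero) that the
    source tables render as bolding.
    """
    tu = bundle["time_use_table"]
    tu_fmt = pd.DataFrame(
        {
            "behaviour_set": tu["behaviour_set"],
            "raw_mean_sd": [
                f"{m:.0f} ({s:.2f})" for m, s in zip(tu["raw_mean"], tu["raw_sd"])
            ],
            "geometric_mean": [f"{g:.0f}" for g in tu["geometric_mean"]],
            "percent_of_day": tu["percent_of_day"].astype(int),
        }
    )
    pw = bundle["pairwise"]
    pw_fmt = pd.DataFrame(
        {
            "add": pw["add"],
            "remove": pw["remove"],
            "delta": pw["delta"],
            "beta": [("" if not f else f"{b:.2f}") for b, f in zip(pw["beta"], pw["feasible"])],
            "ci_95": [
                ("infeasible" if not f else f"({lo:.2f} to {hi:.2f})")
                for lo, hi, f in zip(pw["ci_low"], pw["ci_high"], pw["feasible"])
            ],
            "significant": pw["significant"],
        }
    )
    return {"time_use_formatted": tu_fmt, "substitutions_formatted": pw_fmt}
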