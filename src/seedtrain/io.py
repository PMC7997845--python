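"""Readers/writers for measurement and result formats, plus run configs.

The measurement interchange format is a tidy CSV with columns
``seed_train_id, scale_id, time_h, variable, value`` (scale-local time,
variables Xv/Via/cGlc/cGln/cLac/cAmm).  Run configuration is a single
YAML file validated strictly: unknown keys are rejected, and every run
writes its fully resolved config next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinetic_model import CultureState, KineticParameters, PARAMETER_NAMES, Trajectory
from .seed_train import (
    MEASURED_VARIABLES,
    PassagingRule,
    ScaleDefinition,
    SeedTrainRecord,
    default_fresh_medium,
    default_scales,
)
from .synthetic_data import VariabilityConfig, nominal_parameters
from .workflow import WorkflowConfig

__all__ = [
    "read_seed_train_csv",
    "write_seed_train_csv",
    "write_trajectory_csv",
    "write_parameters_json",
    "read_parameters_json",
    "RunConfig",
    "load_config",
]

REQUIRED_COLUMNS = ("seed_train_id", "scale_id", "time_h", "variable", "value")


def read_seed_train_csv(
    path: str | Path, scales: Sequence[ScaleDefinition] | None = None
) -> list[SeedTrainRecord]:
    """Parse a tidy measurement CSV into one record per seed train.

    Rows are grouped by seed_train_id and scale_id and sorted by time.
    Duplicate (id, scale, time, variable) rows, a wrong header, unknown
    variables or non-numeric values are rejected with the offending row
    number (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_var = ~df["variable"].isin(MEASURED_VARIABLES)
    if bad_var.any():
        row = int(df.index[bad_var][0]) + 1
        raise ValueError(
            f"{path}: unknown variable {df.loc[df.index[bad_var][0], 'variable']!r} at row {row}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    nonnum = values.isna() & df["value"].notna()
    if nonnum.any():
        row = int(df.index[nonnum][0]) + 1
        raise ValueError(f"{path}: non-numeric value at row {row}")
    df["value"] = values
    dup = df.duplicated(subset=["seed_train_id", "scale_id", "time_h", "variable"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValueError(f"{path}: duplicate measurement row at row {row}")
    scales = list(scales) if scales is not None else default_scales()
    records = []
    for train_id, grp in df.groupby("seed_train_id", sort=True):
        records.append(
            SeedTrainRecord(
                seed_train_id=str(train_id),
                scales=tuple(scales),
                measurements=grp[["scale_id", "time_h", "variable", "value"]].reset_index(
                    drop=True
                ),
            )
        )
    return records


def write_seed_train_csv(records: Sequence[SeedTrainRecord], path: str | Path) -> None:
    frames = []
    for rec in records:
        df = rec.measurements.copy()
        df.insert(0, "seed_train_id", rec.seed_train_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Tidy wide export: time_h, Xt, Xv, Via, cGlc, cGln, cLac, cAmm."""
    traj.to_frame().to_csv(path, index=False)


def write_parameters_json(params: KineticParameters, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1) + "\n")


def read_parameters_json(path: str | Path) -> KineticParameters:
    data = json.loads(Path(path).read_text())
    unknown = set(data) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return KineticParameters(**data)


class ScaleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scale_id: int
    working_volume_L: float
    duration_h: float
    sampling_interval_h: float = 24.0


class PassagingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["target_inoculation_density", "fixed_split_ratio"] = (
        "target_inoculation_density"
    )
    target_Xv: float = 0.4
    transfer_fraction: float | None = None


class MediumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cGlc: float = 30.0
    cGln: float = 4.0


class VariabilitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    measurement_cv: float = 0.05
    intermediate_precision_cv: float = 0.047
    batch_mu_max_cv: float = 0.05
    scale1_mu_max_factor: float = 0.93


class WorkflowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    objective: Literal["wlse", "mhe"] = "wlse"
    horizon_mode: Literal["growing", "moving", "per_scale_growing"] = "growing"
    horizon_length: int | None = None
    parameter_sets: Literal["shared", "per_scale"] = "shared"
    arrival_cost_window_B: int = 0
    evaluation_start: int = 2
    gamma: float = 1.0
    bound_fraction: float = 0.5
    forgetting_form: Literal["model", "measured"] = "model"
    n_starts: int = 1
    max_evals: int = 2000

    @model_validator(mode="after")
    def _consistent(self):
        if self.horizon_mode == "moving" and (self.horizon_length or 0) < 2:
            raise ValueError("moving horizon requires horizon_length >= 2")
        return self


class RunConfig(BaseModel):
    """Validated, composable run configuration (strict: unknown keys fail)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_seed_trains: int = 10
    scales: list[ScaleConfig] = Field(
        default_factory=lambda: [
            ScaleConfig(scale_id=1, working_volume_L=40, duration_h=96),
            ScaleConfig(scale_id=2, working_volume_L=320, duration_h=72),
            ScaleConfig(scale_id=3, working_volume_L=2160, duration_h=72),
        ]
    )
    passaging: PassagingConfig = Field(default_factory=PassagingConfig)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    variability: VariabilitySection = Field(default_factory=VariabilitySection)
    workflow: WorkflowSection = Field(default_factory=WorkflowSection)
    parameters: dict[str, float] | None = None

    def build_scales(self) -> list[ScaleDefinition]:
        medium = default_fresh_medium(self.medium.cGlc, self.medium.cGln)
        return [
            ScaleDefinition(
                s.scale_id, s.working_volume_L, s.duration_h, s.sampling_interval_h, medium
            )
            for s in self.scales
        ]

    def build_rule(self) -> PassagingRule:
        return PassagingRule(
            mode=self.passaging.mode,
            target_Xv=self.passaging.target_Xv,
            transfer_fraction=self.passaging.transfer_fraction,
        )

    def build_variability(self) -> VariabilityConfig:
        v = self.variability
        return VariabilityConfig(
            measurement_cv=v.measurement_cv,
            intermediate_precision_cv=v.intermediate_precision_cv,
            batch_mu_max_cv=v.batch_mu_max_cv,
            scale1_mu_max_factor=v.scale1_mu_max_factor,
            rng_seed=self.seed,
        )

    def build_workflow(self) -> WorkflowConfig:
        w = self.workflow
        return WorkflowConfig(
            objective=w.objective,
            horizon_mode=w.horizon_mode,
            horizon_length=w.horizon_length,
            parameter_sets=w.parameter_sets,
            arrival_cost_window_B=w.arrival_cost_window_B,
            evaluation_start=w.evaluation_start,
            gamma=w.gamma,
            bound_fraction=w.bound_fraction,
            forgetting_form=w.forgetting_form,
            n_starts=w.n_starts,
            max_evals=w.max_evals,
        )

    def build_parameters(self) -> KineticParameters:
        nominal = nominal_parameters()
        if self.parameters:
            nominal = nominal.with_values(**self.parameters)
        return nominal

    def dump_resolved(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
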