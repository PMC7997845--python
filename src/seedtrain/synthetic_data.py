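"""Synthetic seed-train data with the error structure of industrial runs.

Industrial seed-train measurements are proprietary, so this module
emulates them: three bioreactor scales (40 L -> 320 L -> 2160 L), daily
offline sampling over 72-96 h per scale, ~5% multiplicative measurement
error on every observed variable, batch-to-batch variability of the
maximum growth rate, and a systematically lower (default -7%) mu_max in
the first stirred scale, where cells still adapt from the shaken to the
stirred cultivation system.

The nominal kinetic parameters and inoculation state below are artifact
defaults chosen to give realistic 3-4 day exponential CHO batch
profiles (inoculation at 0.4e6 cells/mL, 30 mM glucose, 4 mM glutamine,
substantial but incomplete substrate depletion per scale); the emulated
industrial process publishes no numeric values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetic_model import CultureState, KineticParameters, Trajectory
from .seed_train import (
    MEASURED_VARIABLES,
    PassagingRule,
    ScaleDefinition,
    SeedTrainRecord,
    default_scales,
    simulate_seed_train,
)

__all__ = [
    "VariabilityConfig",
    "GroundTruth",
    "nominal_parameters",
    "nominal_initial_state",
    "draw_batch_parameters",
    "generate_seed_train",
    "generate_ensemble",
    "corrupt_measurement",
]

logger = logging.getLogger(__name__)


def nominal_parameters() -> KineticParameters:
    """Nominal (prior) kinetics of the emulated CHO batch process."""
    return KineticParameters(
        mu_max=0.029,       # 1/h  (~24 h doubling time)
        mu_d_max=0.02,      # 1/h  death acceleration at glucose exhaustion
        mu_d_min=0.0004,    # 1/h  basal death rate
        K_Glc=1.0,          # mM
        K_Gln=0.3,          # mM
        k_Glc=1.0,          # mM
        k_Gln=0.3,          # mM
        q_Glc_max=0.14,     # mmol/(1e9 cells h)
        q_Gln_max=0.020,    # mmol/(1e9 cells h)
        Y_LacGlc=1.4,       # mol/mol
        Y_AmmGln=0.65,      # mol/mol
        k_lys=0.001,        # 1/h
        k_Gln_decomp=0.0024,  # 1/h  abiotic glutamine degradation at 37 C
        K_d_Glc=0.2,        # mM
    )


def nominal_initial_state() -> CultureState:
    """Inoculation state of scale 1 (fresh medium, ~98% viability)."""
    return CultureState(Xt=0.408, Xv=0.4, cGlc=30.0, cGln=4.0, cLac=0.1, cAmm=0.08)


@dataclass(frozen=True)
class VariabilityConfig:
    """Statistical structure of the emulated measurements.

    * ``measurement_cv`` — multiplicative error per measured cell (~5%).
    * ``intermediate_precision_cv`` — within-lab reproducibility of the
      cell-density assay (4.7%); used for precision-weighted reporting,
      not for noise generation.
    * ``batch_mu_max_cv`` — run-to-run spread of the maximum growth rate.
    * ``scale1_mu_max_factor`` — systematic mu_max reduction in the first
      stirred scale (0.93 = 7% lower than scales 2-3).
    """

    measurement_cv: float = 0.05
    intermediate_precision_cv: float = 0.047
    batch_mu_max_cv: float = 0.05
    scale1_mu_max_factor: float = 0.93
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("measurement_cv", "intermediate_precision_cv", "batch_mu_max_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.scale1_mu_max_factor <= 1:
            raise ValueError("scale1_mu_max_factor must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True per-scale parameters and noiseless trajectories behind a record."""

    params_per_scale: tuple[KineticParameters, ...]
    trajectories: tuple[Trajectory, ...]
    initial_state: CultureState


def draw_batch_parameters(
    nominal: KineticParameters,
    var: VariabilityConfig,
    rng: np.random.Generator,
    n_scales: int = 3,
    per_parameter_cv: dict[str, float] | None = None,
) -> list[KineticParameters]:
    """True parameter sets of one seed train, one per scale.

    The seed train draws a single mu_max (nominal times a truncated-
    positive Gaussian factor with CV ``batch_mu_max_cv``) shared by all
    scales; the first-scale copy is additionally multiplied by
    ``scale1_mu_max_factor``.  Other parameters stay nominal unless
    ``per_parameter_cv`` assigns them their own CV.
    """
    factor = 1.0 + var.batch_mu_max_cv * rng.standard_normal()
    while factor <= 0:
        factor = 1.0 + var.batch_mu_max_cv * rng.standard_normal()
    mu = nominal.mu_max * factor
    extra = {}
    for name, cv in (per_parameter_cv or {}).items():
        f = 1.0 + cv * rng.standard_normal()
        while f <= 0:
            f = 1.0 + cv * rng.standard_normal()
        extra[name] = getattr(nominal, name) * f
    base = nominal.with_values(mu_max=mu, **extra)
    out = []
    for s in range(n_scales):
        if s == 0:
            out.append(base.with_values(mu_max=mu * var.scale1_mu_max_factor))
        else:
            out.append(base)
    return out


def generate_seed_train(
    params_per_scale: Sequence[KineticParameters],
    scales: Sequence[ScaleDefinition],
    rule: PassagingRule,
    var: VariabilityConfig,
    rng: np.random.Generator,
    seed_train_id: str = "ST1",
    init: CultureState | None = None,
) -> tuple[SeedTrainRecord, GroundTruth]:
    """One noisy measurement record plus its ground truth.

    Noiseless trajectories are simulated per scale (with passaging) and
    sampled on each scale's daily grid including inoculation; every
    emitted cell gets independent multiplicative Gaussian noise
    ``value * (1 + N(0, measurement_cv))``.  Draws that would turn a
    positive value negative are redrawn (logged); exact zeros stay zero.
    """
    init = init if init is not None else nominal_initial_state()
    trajs = simulate_seed_train(init, params_per_scale, scales, rule)
    rows: list[dict] = []
    for scale, traj in zip(scales, trajs):
        clean = {
            "Xv": traj.column("Xv"),
            "Via": traj.viability,
            "cGlc": traj.column("cGlc"),
            "cGln": traj.column("cGln"),
            "cLac": traj.column("cLac"),
            "cAmm": traj.column("cAmm"),
        }
        for r, t in enumerate(traj.times):
            for var_name in MEASURED_VARIABLES:
                true_val = float(clean[var_name][r])
                noisy = _noisy(true_val, var.measurement_cv, rng)
                rows.append(
                    {
                        "scale_id": scale.scale_id,
                        "time_h": float(t),
                        "variable": var_name,
                        "value": noisy,
                    }
                )
    record = SeedTrainRecord(
        seed_train_id=seed_train_id,
        scales=tuple(scales),
        measurements=pd.DataFrame(rows),
    )
    truth = GroundTruth(
        params_per_scale=tuple(params_per_scale),
        trajectories=tuple(trajs),
        initial_state=init,
    )
    return record, truth


def _noisy(value: float, cv: float, rng: np.random.Generator) -> float:
    if cv == 0 or value == 0:
        return value
    out = value * (1.0 + cv * rng.standard_normal())
    tries = 0
    while out < 0:
        tries += 1
        out = value * (1.0 + cv * rng.standard_normal())
    if tries:
        logger.debug("resampled %d negative noise draws for value %.4g", tries, value)
    return out


def generate_ensemble(
    n_seed_trains: int,
    var: VariabilityConfig,
    scales: Sequence[ScaleDefinition] | None = None,
    rule: PassagingRule | None = None,
    nominal: KineticParameters | None = None,
    init: CultureState | None = None,
    seed: int | None = None,
) -> tuple[list[SeedTrainRecord], list[GroundTruth]]:
    """An ensemble of independent seed trains (default study size: 10)."""
    scales = list(scales) if scales is not None else default_scales()
    rule = rule if rule is not None else PassagingRule()
    nominal = nominal if nominal is not None else nominal_parameters()
    rng = np.random.default_rng(var.rng_seed if seed is None else seed)
    records, truths = [], []
    for m in range(n_seed_trains):
        params = draw_batch_parameters(nominal, var, rng, n_scales=len(scales))
        rec, truth = generate_seed_train(
            params, scales, rule, var, rng, seed_train_id=f"ST{m + 1}", init=init
        )
        records.append(rec)
        truths.append(truth)
    return records, truths


def corrupt_measurement(
    record: SeedTrainRecord,
    scale_id: int,
    time_index: int,
    variable: str,
    relative_bias: float,
) -> SeedTrainRecord:
    """Multiply one measurement cell by (1 + relative_bias).

    ``time_index`` counts the scale's sampling points (0 = inoculation).
    Used to reproduce the outlier failure mode of very short estimation
    horizons; all other cells are untouched.
    """
    times = sorted(
        record.measurements.loc[
            record.measurements["scale_id"] == scale_id, "time_h"
        ].unique()
    )
    if not 0 <= time_index < len(times):
        raise KeyError(f"scale {scale_id} has no sampling point index {time_index}")
    t = float(times[time_index])
    old = record.value(scale_id, t, variable)
    if not np.isfinite(old):
        raise KeyError(f"no measurement {variable!r} at scale {scale_id}, t = {t} h")
    return record.with_value(scale_id, t, variable, old * (1.0 + relative_bias))
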