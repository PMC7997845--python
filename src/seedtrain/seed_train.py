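"""Seed-train simulation: chained batch cultivations with passaging.

A seed train expands a culture through bioreactors of increasing working
volume (default 40 L -> 320 L -> 2160 L).  At the end of each scale a
fraction of the broth inoculates the next vessel, which is topped up with
fresh medium (ideal instantaneous mixing, no transfer losses).

Sampling is sparse and offline: one sample roughly every 24 h, i.e. 4-5
points per scale including inoculation.  Each scale uses a local clock
that restarts at 0 h at inoculation; a global sampling index runs across
scales in chronological order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .kinetic_model import (
    STATE_NAMES,
    CultureState,
    KineticParameters,
    Trajectory,
    simulate_batch,
)

__all__ = [
    "MEASURED_VARIABLES",
    "ScaleDefinition",
    "PassagingRule",
    "SeedTrainRecord",
    "PassagingError",
    "default_scales",
    "default_fresh_medium",
    "passage",
    "simulate_seed_train",
    "predict_future",
]

#: Offline-measured variables, in canonical column order.
MEASURED_VARIABLES = ("Xv", "Via", "cGlc", "cGln", "cLac", "cAmm")


class PassagingError(ValueError):
    """Infeasible transfer, e.g. target density above the available one."""


def default_fresh_medium(cGlc: float = 30.0, cGln: float = 4.0) -> CultureState:
    """Cell-free medium with typical basal glucose/glutamine levels."""
    return CultureState(Xt=0.0, Xv=0.0, cGlc=cGlc, cGln=cGln, cLac=0.0, cAmm=0.0)


@dataclass(frozen=True)
class ScaleDefinition:
    """One cultivation scale of the seed train.

    ``duration_h`` covers 72-96 h (3-4 days between passages);
    ``sampling_interval_h`` defaults to daily sampling.
    """

    scale_id: int
    working_volume_L: float
    duration_h: float
    sampling_interval_h: float = 24.0
    fresh_medium: CultureState = field(default_factory=default_fresh_medium)

    def __post_init__(self) -> None:
        if self.working_volume_L <= 0 or self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("volume, duration and sampling interval must be positive")

    @property
    def sampling_times(self) -> np.ndarray:
        """Scale-local sampling grid, inoculation (t=0) included."""
        n = int(np.floor(self.duration_h / self.sampling_interval_h + 1e-9))
        return np.arange(n + 1) * self.sampling_interval_h


def default_scales(
    volumes: Sequence[float] = (40.0, 320.0, 2160.0),
    durations: Sequence[float] = (96.0, 72.0, 72.0),
    sampling_interval_h: float = 24.0,
    fresh_medium: CultureState | None = None,
) -> list[ScaleDefinition]:
    if len(volumes) != len(durations):
        raise ValueError("volumes and durations must have equal length")
    if np.any(np.diff(volumes) <= 0):
        raise ValueError("working volumes must strictly increase across scales")
    medium = fresh_medium if fresh_medium is not None else default_fresh_medium()
    return [
        ScaleDefinition(i + 1, float(v), float(d), sampling_interval_h, medium)
        for i, (v, d) in enumerate(zip(volumes, durations))
    ]


@dataclass(frozen=True)
class PassagingRule:
    """How the transfer fraction into the next scale is chosen.

    ``target_inoculation_density`` dilutes to a fixed post-transfer viable
    cell density (standard seed-train practice); ``fixed_split_ratio``
    transfers a fixed volume fraction.
    """

    mode: Literal["target_inoculation_density", "fixed_split_ratio"] = (
        "target_inoculation_density"
    )
    target_Xv: float = 0.4
    transfer_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "target_inoculation_density":
            if self.target_Xv <= 0:
                raise ValueError("target_Xv must be positive")
        elif self.mode == "fixed_split_ratio":
            if self.transfer_fraction is None or not (0 < self.transfer_fraction <= 1):
                raise ValueError("transfer_fraction must lie in (0, 1]")
        else:
            raise ValueError(f"unknown passaging mode {self.mode!r}")

    def fraction(self, end_state: CultureState) -> float:
        if self.mode == "fixed_split_ratio":
            return float(self.transfer_fraction)
        if end_state.Xv <= 0:
            raise PassagingError("cannot reach a positive target density from Xv = 0")
        f = self.target_Xv / end_state.Xv
        if f > 1 + 1e-12:
            raise PassagingError(
                f"target_Xv = {self.target_Xv} exceeds the available density "
                f"Xv = {end_state.Xv:.4g}; dilution cannot concentrate cells"
            )
        return min(f, 1.0)


def passage(
    end_state: CultureState, rule: PassagingRule, next_scale: ScaleDefinition
) -> CultureState:
    """Inoculation state of the next scale by ideal linear mixing.

    A fraction ``f`` of the broth is mixed with ``1 - f`` fresh medium:
    cell densities scale by ``f`` (the viability ratio is preserved) and
    every concentration is the convex combination of broth and medium.
    """
    f = rule.fraction(end_state)
    medium = next_scale.fresh_medium
    mixed = {
        "Xt": f * end_state.Xt,
        "Xv": f * end_state.Xv,
    }
    for name in STATE_NAMES[2:]:
        mixed[name] = f * getattr(end_state, name) + (1 - f) * getattr(medium, name)
    return CultureState(**mixed)


def simulate_seed_train(
    init_scale1: CultureState,
    params_per_scale: Sequence[KineticParameters],
    scales: Sequence[ScaleDefinition],
    rule: PassagingRule,
    times_per_scale: Sequence[np.ndarray] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[Trajectory]:
    """Simulate all scales in sequence, passaging between them.

    One parameter set per scale (the same object may be repeated to model
    a single shared set).  Each returned trajectory uses scale-local time
    starting at 0.
    """
    if len(params_per_scale) != len(scales):
        raise ValueError("need exactly one parameter set per scale")
    trajectories: list[Trajectory] = []
    state = init_scale1
    for s, (scale, params) in enumerate(zip(scales, params_per_scale)):
        grid = (
            np.asarray(times_per_scale[s], dtype=float)
            if times_per_scale is not None
            else scale.sampling_times
        )
        traj = simulate_batch(state, params, grid, rtol=rtol, atol=atol)
        trajectories.append(traj)
        if s + 1 < len(scales):
            state = passage(traj.final_state(), rule, scales[s + 1])
    return trajectories


@dataclass(frozen=True)
class SeedTrainRecord:
    """Offline measurement series of one seed-train run.

    ``measurements`` is tidy: columns scale_id, time_h (scale-local),
    variable, value.  The global sampling index orders points by scale,
    then by local time.
    """

    seed_train_id: str
    scales: tuple[ScaleDefinition, ...]
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(self.scales))
        df = self.measurements
        required = {"scale_id", "time_h", "variable", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"measurements need columns {sorted(required)}")
        dup = df.duplicated(subset=["scale_id", "time_h", "variable"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate measurement for scale {row['scale_id']}, "
                f"t = {row['time_h']} h, variable {row['variable']!r}"
            )
        tidy = df.sort_values(["scale_id", "time_h", "variable"], kind="mergesort")
        object.__setattr__(self, "measurements", tidy.reset_index(drop=True))

    @property
    def sampling_points(self) -> list[tuple[int, float]]:
        """Ordered global list of (scale_id, scale-local time)."""
        pts = self.measurements[["scale_id", "time_h"]].drop_duplicates()
        return [(int(r.scale_id), float(r.time_h)) for r in pts.itertuples()]

    @property
    def n_points(self) -> int:
        return len(self.sampling_points)

    def scale_index_of(self, index: int) -> int:
        """0-based scale position of global sampling point ``index``."""
        scale_id = self.sampling_points[index][0]
        for i, sc in enumerate(self.scales):
            if sc.scale_id == scale_id:
                return i
        raise KeyError(f"scale_id {scale_id} not among the record's scales")

    def value(self, scale_id: int, time_h: float, variable: str) -> float:
        df = self.measurements
        m = (
            (df["scale_id"] == scale_id)
            & (np.isclose(df["time_h"], time_h))
            & (df["variable"] == variable)
        )
        hit = df.loc[m, "value"]
        if hit.empty:
            return float("nan")
        return float(hit.iloc[0])

    def values_matrix(
        self, indices: Sequence[int], variables: Sequence[str] = MEASURED_VARIABLES
    ) -> np.ndarray:
        """(len(indices), len(variables)) measurement matrix, NaN if absent."""
        pts = self.sampling_points
        out = np.full((len(indices), len(variables)), np.nan)
        for r, idx in enumerate(indices):
            scale_id, t = pts[idx]
            for c, var in enumerate(variables):
                out[r, c] = self.value(scale_id, t, var)
        return out

    def state_at(self, index: int) -> CultureState:
        """Measured culture state at a global sampling point.

        Total density is derived from measured Xv and viability
        (Xt = Xv / (Via/100)); measurement noise can push apparent
        viability slightly above 100%, in which case Xt is floored at Xv.
        """
        scale_id, t = self.sampling_points[index]
        vals = {var: self.value(scale_id, t, var) for var in MEASURED_VARIABLES}
        for var in ("Xv", "cGlc", "cGln", "cLac", "cAmm"):
            if not np.isfinite(vals[var]):
                raise ValueError(
                    f"missing measurement {var!r} at scale {scale_id}, t = {t} h "
                    f"of seed train {self.seed_train_id!r}"
                )
        via = vals["Via"]
        if np.isfinite(via) and via > 0:
            Xt = max(vals["Xv"] / (via / 100.0), vals["Xv"])
        else:
            Xt = vals["Xv"]
        return CultureState(
            Xt=Xt,
            Xv=vals["Xv"],
            cGlc=vals["cGlc"],
            cGln=vals["cGln"],
            cLac=vals["cLac"],
            cAmm=vals["cAmm"],
        )

    def with_value(
        self, scale_id: int, time_h: float, variable: str, value: float
    ) -> "SeedTrainRecord":
        df = self.measurements.copy()
        m = (
            (df["scale_id"] == scale_id)
            & (np.isclose(df["time_h"], time_h))
            & (df["variable"] == variable)
        )
        if not m.any():
            raise KeyError(
                f"no measurement for scale {scale_id}, t = {time_h} h, {variable!r}"
            )
        df.loc[m, "value"] = value
        return replace(self, measurements=df)


def predict_future(
    record: SeedTrainRecord,
    params_per_scale: Sequence[KineticParameters],
    current_time_index: int,
    anchor_policy: Literal["measured_anchors", "simulated_passaging"] = "measured_anchors",
    rule: PassagingRule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Model prediction at all sampling points after ``current_time_index``.

    The simulation restarts from the *measured* state at the current
    sampling point.  At each later scale boundary the initial state is
    either reset to that scale's measured inoculation state
    (``measured_anchors``, the study default: scale-initial concentrations
    are treated as known) or computed by :func:`passage`
    (``simulated_passaging``, requires ``rule``).

    Returns a tidy frame: scale_id, time_h, variable, predicted.  Empty
    if the current point is the last one.
    """
    pts = record.sampling_points
    if not 0 <= current_time_index < len(pts):
        raise IndexError("current_time_index outside the record")
    if len(params_per_scale) != len(record.scales):
        raise ValueError("need one parameter set per scale")
    if anchor_policy == "simulated_passaging" and rule is None:
        raise ValueError("simulated_passaging requires a passaging rule")

    rows: list[dict] = []
    cur_scale_pos = record.scale_index_of(current_time_index)
    state = record.state_at(current_time_index)
    t_now = pts[current_time_index][1]
    carry_state: CultureState | None = None

    for s in range(cur_scale_pos, len(record.scales)):
        scale = record.scales[s]
        scale_times = sorted(t for sid, t in pts if sid == scale.scale_id)
        if s == cur_scale_pos:
            start_t = t_now
            start_state = state
            future_times = [t for t in scale_times if t > t_now + 1e-9]
        else:
            start_t = scale_times[0]
            if anchor_policy == "measured_anchors":
                idx0 = next(
                    i
                    for i, (sid, t) in enumerate(pts)
                    if sid == scale.scale_id and np.isclose(t, start_t)
                )
                start_state = record.state_at(idx0)
            else:
                start_state = passage(carry_state, rule, scale)
            # the scale-initial point itself belongs to the prediction horizon
            rows.extend(
                _state_rows(scale.scale_id, start_t, start_state.to_array())
            )
            future_times = [t for t in scale_times if t > start_t + 1e-9]
        grid = np.array([start_t] + future_times, dtype=float)
        if grid.size >= 2:
            traj = simulate_batch(start_state, params_per_scale[s], grid, rtol=rtol, atol=atol)
            for r, t in enumerate(grid[1:], start=1):
                rows.extend(_state_rows(scale.scale_id, t, traj.states[r]))
            carry_state = traj.final_state()
        else:
            carry_state = start_state

    return pd.DataFrame(rows, columns=["scale_id", "time_h", "variable", "predicted"])


def _state_rows(scale_id: int, t: float, y: np.ndarray) -> list[dict]:
    state = CultureState.from_array(np.clip(y, 0.0, None))
    vals = {
        "Xv": state.Xv,
        "Via": state.viability,
        "cGlc": state.cGlc,
        "cGln": state.cGln,
        "cLac": state.cLac,
        "cAmm": state.cAmm,
    }
    return [
        {"scale_id": scale_id, "time_h": float(t), "variable": var, "predicted": float(v)}
        for var, v in vals.items()
    ]
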