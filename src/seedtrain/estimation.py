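"""Parameter re-estimation objectives and the bounded optimizer.

Two objectives are provided for model updating at a sampling point:

* **WLSE** — weighted least squares over the estimation horizon,

  ``J(p) = sum_j sum_i w_m,ij (y_m,ij - y_ij(p))^2``

  with per-variable weights ``w_m,ij = 1 / y_j,max`` (division by the
  maximum experimental value of the variable over the horizon).

* **MHE** — a squared-error moving-horizon objective adding two prior
  terms: a *forgetting term* penalising the deviation of the current
  model values from the prior model values (simulated with the prior
  parameter vector), and a penalty on parameter change,

  ``J(p) = WLSE(p) + sum_ij w_p (y_ij(p) - yhat_ij)^2 + dp * c_dp``

  with ``dp = (gamma / n_p) ||phat_s - p_s||_2`` on [0,1]-scaled
  parameter vectors.  The default weights shrink with the horizon length
  ``n``: ``w_p = 4/n`` and ``c_dp = 1/n``, so prior knowledge dominates
  when only two or three points are available and fades as data accrue.

The forgetting term is sometimes written against the *measured* values,
``(y_m - yhat)^2``, which is constant in ``p`` and cannot steer the
optimizer; that variant is kept behind ``forgetting_form='measured'``
for reproducing objective values, while the default penalises the
model-vs-prior deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .kinetic_model import FreeParameterSpec, KineticParameters

__all__ = [
    "MeasurementWindow",
    "PriorInfo",
    "EstimationProblem",
    "EstimationResult",
    "measurement_weights",
    "wlse_objective",
    "mhe_objective",
    "scale_parameters",
    "unscale_parameters",
    "parameter_penalty",
    "forgetting_weight",
    "penalty_weight",
    "select_horizon",
    "estimate",
]


def measurement_weights(y_m: np.ndarray) -> np.ndarray:
    """Per-variable weights 1 / max(y) — constant down each column.

    Missing entries (NaN) are ignored when taking the maximum; a column
    without a positive finite value has no usable scale and is rejected.
    """
    y = np.asarray(y_m, dtype=float)
    if y.ndim != 2:
        raise ValueError("y_m must be 2-D (n points x k variables)")
    col_max = np.max(np.where(np.isfinite(y), y, -np.inf), axis=0)
    if np.any(~np.isfinite(col_max)) or np.any(col_max <= 0):
        bad = [int(j) for j in np.flatnonzero(~(np.isfinite(col_max) & (col_max > 0)))]
        raise ValueError(f"columns {bad} have no positive finite value to scale by")
    return np.broadcast_to(1.0 / col_max, y.shape).copy()


@dataclass(frozen=True)
class MeasurementWindow:
    """Measurements of the estimation horizon: ``n`` sampling points by
    ``k`` observed variables, with per-entry weights.

    NaN entries mark missing measurements; they drop out of every sum.
    ``n`` counts sampling *times*, not cells.
    """

    times: np.ndarray
    y_m: np.ndarray
    variable_names: tuple[str, ...]
    w_m: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y_m, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y_m", y)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        if t.size < 2:
            raise ValueError("an estimation horizon needs at least 2 sampling points")
        if y.shape != (t.size, len(self.variable_names)):
            raise ValueError("y_m shape must be (n times, k variables)")
        w = self.w_m if self.w_m is not None else measurement_weights(y)
        w = np.asarray(w, dtype=float)
        if w.shape != y.shape:
            raise ValueError("w_m shape must match y_m")
        if np.any(np.isfinite(y) & ~(w > 0)):
            raise ValueError("weights must be positive wherever a measurement is present")
        object.__setattr__(self, "w_m", w)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.y_m)


@dataclass(frozen=True)
class PriorInfo:
    """Prior knowledge entering the MHE objective.

    ``p_hat`` is the prior free-parameter vector; ``y_hat`` holds the
    model values simulated with ``p_hat`` on the window grid.  ``w_p``
    weights the forgetting term, ``c_dp`` the parameter-change penalty,
    and ``gamma`` is the penalty's tuning constant.
    """

    p_hat: np.ndarray
    y_hat: np.ndarray
    w_p: float
    c_dp: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_hat", np.asarray(self.p_hat, dtype=float))
        object.__setattr__(self, "y_hat", np.asarray(self.y_hat, dtype=float))
        if self.w_p < 0 or self.c_dp < 0 or self.gamma < 0:
            raise ValueError("w_p, c_dp and gamma must be >= 0")


@dataclass
class EstimationProblem:
    """Everything one objective evaluation needs.

    ``simulator`` maps a free-parameter vector to model values on the
    window grid (n x k), handling batch integration and any passaging or
    re-anchoring internally; it must be deterministic.
    """

    window: MeasurementWindow
    free_spec: FreeParameterSpec
    fixed_params: KineticParameters
    start_values: np.ndarray
    simulator: Callable[[np.ndarray], np.ndarray]
    prior: PriorInfo | None = None

    def __post_init__(self) -> None:
        self.start_values = np.asarray(self.start_values, dtype=float)
        if self.start_values.size != self.free_spec.n_p:
            raise ValueError("start_values length must match the free-parameter spec")
        if np.any(self.start_values < self.free_spec.lower - 1e-12) or np.any(
            self.start_values > self.free_spec.upper + 1e-12
        ):
            raise ValueError("start_values must lie within the bounds")
        if self.prior is not None and self.prior.y_hat.shape != self.window.y_m.shape:
            raise ValueError("prior.y_hat shape must match the measurement window")


@dataclass(frozen=True)
class EstimationResult:
    p_opt: np.ndarray
    J_opt: float
    n_evals: int
    converged: bool
    active_bounds: tuple[str, ...] = ()

    def free_dict(self, names: Sequence[str]) -> dict[str, float]:
        return dict(zip(names, map(float, self.p_opt)))


def wlse_objective(p: np.ndarray, problem: EstimationProblem) -> float:
    """Weighted least squares over the present (i, j) entries."""
    w = problem.window
    y = problem.simulator(np.asarray(p, dtype=float))
    mask = w.mask
    resid = np.where(mask, w.y_m - y, 0.0)
    return float(np.sum(w.w_m[mask] * resid[mask] ** 2))


def scale_parameters(p: np.ndarray, free_spec: FreeParameterSpec) -> np.ndarray:
    """Affine map of each component onto [0, 1] over its bound interval."""
    p = np.asarray(p, dtype=float)
    span = free_spec.upper - free_spec.lower
    if np.any(span <= 0):
        raise ValueError("degenerate bounds (upper == lower) cannot be scaled")
    return (p - free_spec.lower) / span


def unscale_parameters(p_s: np.ndarray, free_spec: FreeParameterSpec) -> np.ndarray:
    p_s = np.asarray(p_s, dtype=float)
    return free_spec.lower + p_s * (free_spec.upper - free_spec.lower)


def parameter_penalty(
    p: np.ndarray,
    p_hat: np.ndarray,
    free_spec: FreeParameterSpec,
    gamma: float = 1.0,
) -> float:
    """Scaled parameter-change distance (gamma / n_p) * ||phat_s - p_s||_2."""
    ps = scale_parameters(p, free_spec)
    ps_hat = scale_parameters(p_hat, free_spec)
    return float(gamma / free_spec.n_p * np.linalg.norm(ps_hat - ps))


def forgetting_weight(n: int) -> float:
    """Forgetting-term weight w_p = 4/n for a horizon of n points."""
    if n < 1:
        raise ValueError("horizon length must be >= 1")
    return 4.0 / n


def penalty_weight(n: int) -> float:
    """Parameter-penalty weight c_dp = 1/n for a horizon of n points."""
    if n < 1:
        raise ValueError("horizon length must be >= 1")
    return 1.0 / n


def mhe_objective(
    p: np.ndarray,
    problem: EstimationProblem,
    forgetting_form: Literal["model", "measured"] = "model",
) -> float:
    """Moving-horizon objective: WLSE + forgetting term + parameter penalty.

    ``forgetting_form='model'`` (default) penalises
    ``w_p (y_ij(p) - yhat_ij)^2`` — the deviation of current from prior
    model values, which is the form that actually regularises the
    estimate.  ``'measured'`` uses ``w_p (y_m,ij - yhat_ij)^2`` instead,
    a p-independent offset retained only for reproducing J values.
    """
    if problem.prior is None:
        raise ValueError("mhe_objective requires prior information")
    prior = problem.prior
    w = problem.window
    p = np.asarray(p, dtype=float)
    y = problem.simulator(p)
    mask = w.mask
    resid = np.where(mask, w.y_m - y, 0.0)
    J = float(np.sum(w.w_m[mask] * resid[mask] ** 2))
    if forgetting_form == "model":
        forget = np.where(mask, y - prior.y_hat, 0.0)
    elif forgetting_form == "measured":
        forget = np.where(mask, w.y_m - prior.y_hat, 0.0)
    else:
        raise ValueError(f"unknown forgetting_form {forgetting_form!r}")
    J += float(prior.w_p * np.sum(forget[mask] ** 2))
    dp = parameter_penalty(p, prior.p_hat, problem.free_spec, prior.gamma)
    return J + dp * prior.c_dp


def select_horizon(
    all_indices: Sequence[int],
    current_index: int,
    mode: Literal["growing", "moving", "per_scale_growing"],
    fixed_length: int | None = None,
    scale_map: Sequence[int] | None = None,
) -> list[int]:
    """Estimation-horizon indices at the current sampling point.

    ``all_indices`` are the global sampling indices in chronological
    order (0-based); ``current_index`` must be at least the second one.

    * ``growing`` — everything from the first point up to the current one
      (fixed left bound).
    * ``moving`` — the ``fixed_length`` most recent points; the oldest
      point drops out as a new one arrives (fewer while not yet
      ``fixed_length`` available).
    * ``per_scale_growing`` — all points of the current scale up to the
      current one (left bound resets at each scale start); requires
      ``scale_map`` giving each index's scale.
    """
    idx = list(all_indices)
    if current_index not in idx:
        raise ValueError("current_index must be one of all_indices")
    pos = idx.index(current_index)
    if pos < 1:
        raise ValueError("no estimation before the second data point")
    upto = idx[: pos + 1]
    if mode == "growing":
        return upto
    if mode == "moving":
        if fixed_length is None or fixed_length < 1:
            raise ValueError("moving mode requires a positive fixed_length")
        return upto[-fixed_length:]
    if mode == "per_scale_growing":
        if scale_map is None:
            raise ValueError("per_scale_growing requires a scale_map")
        cur_scale = scale_map[pos]
        return [i for k, i in enumerate(upto) if scale_map[k] == cur_scale]
    raise ValueError(f"unknown horizon mode {mode!r}")


def _residuals_scaled(
    problem: EstimationProblem,
    objective: str,
    forgetting_form: str,
):
    """Residual vector (in [0,1]-scaled coordinates) whose sum of squares
    matches the objective, up to the p-independent offset of the
    ``measured`` forgetting form and an O(1e-18) smoothing of the
    parameter-change penalty at zero distance."""
    w = problem.window
    mask = w.mask
    sqrt_wm = np.sqrt(w.w_m[mask])
    prior = problem.prior
    spec = problem.free_spec

    def resid(x: np.ndarray) -> np.ndarray:
        p = unscale_parameters(np.clip(x, 0.0, 1.0), spec)
        y = problem.simulator(p)
        parts = [sqrt_wm * (w.y_m[mask] - y[mask])]
        if objective == "mhe":
            if forgetting_form == "model":
                parts.append(np.sqrt(prior.w_p) * (y[mask] - prior.y_hat[mask]))
            d = scale_parameters(prior.p_hat, spec) - np.clip(x, 0.0, 1.0)
            nrm = np.sqrt(np.sum(d * d) + 1e-18)
            parts.append(
                np.sqrt(prior.c_dp * prior.gamma / spec.n_p) * d / np.sqrt(nrm)
            )
        return np.concatenate(parts)

    return resid


def estimate(
    problem: EstimationProblem,
    objective: Literal["wlse", "mhe"] = "wlse",
    n_starts: int = 3,
    max_evals: int = 2000,
    xatol: float = 1e-4,
    fatol: float = 1e-8,
    forgetting_form: Literal["model", "measured"] = "model",
) -> EstimationResult:
    """Bounded minimization of the chosen objective.

    Optimization happens in the [0,1]^n_p scaled space (affine transform
    of the bound box).  Up to three deterministic Nelder-Mead starts
    guard against local minima: the supplied start values, then the
    lower- and upper-quartile points of the box.  Because both
    objectives are (near) sums of squares, the best simplex point is
    then polished with a bounded trust-region least-squares step — the
    simplex alone collapses long before converging along weakly
    identifiable directions such as Monod constants far below the
    substrate level.  The polish minimizes the exact objective for WLSE;
    for MHE the parameter-change penalty enters as a smoothed residual
    (the ``measured`` forgetting form is constant in ``p`` and drops out
    of the polish).  Every candidate is accepted on the exact objective,
    and the result never exceeds the objective at the start values.
    """
    if objective == "wlse":
        fun = lambda p: wlse_objective(p, problem)
    elif objective == "mhe":
        fun = lambda p: mhe_objective(p, problem, forgetting_form=forgetting_form)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    spec = problem.free_spec
    n_p = spec.n_p
    evals = 0

    def fun_scaled(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return fun(unscale_parameters(np.clip(x, 0.0, 1.0), spec))

    x0 = scale_parameters(problem.start_values, spec)
    starts = [x0, np.full(n_p, 0.25), np.full(n_p, 0.75)][: max(1, n_starts)]
    budget = max(max_evals // len(starts), 50)

    best_x = x0
    best_J = fun_scaled(x0)
    J_start = best_J
    converged = False
    for s in starts:
        res = minimize(
            fun_scaled,
            s,
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * n_p,
            options={
                "maxfev": budget,
                "xatol": xatol,
                "fatol": fatol,
                "adaptive": n_p > 4,
            },
        )
        if res.fun < best_J:
            best_J = float(res.fun)
            best_x = np.clip(res.x, 0.0, 1.0)
        converged = converged or bool(res.success)

    resid = _residuals_scaled(problem, objective, forgetting_form)

    def count_resid(x):
        nonlocal evals
        evals += 1
        return resid(x)

    try:
        ls = least_squares(
            count_resid,
            best_x,
            bounds=(0.0, 1.0),
            method="trf",
            diff_step=1e-4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=100,
        )
        J_polished = fun_scaled(np.clip(ls.x, 0.0, 1.0))
        if np.isfinite(J_polished) and J_polished < best_J:
            best_J = J_polished
            best_x = np.clip(ls.x, 0.0, 1.0)
            converged = converged or bool(ls.status > 0)
    except Exception:  # polish is best-effort; the simplex result stands
        pass

    if best_J > J_start:  # optimizer contract: never worse than the start
        best_J, best_x = J_start, x0
    p_opt = unscale_parameters(best_x, spec)
    active = tuple(
        name
        for name, xs in zip(spec.names, best_x)
        if xs <= 1e-6 or xs >= 1 - 1e-6
    )
    return EstimationResult(
        p_opt=p_opt,
        J_opt=float(best_J),
        n_evals=evals,
        converged=converged,
        active_bounds=active,
    )
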