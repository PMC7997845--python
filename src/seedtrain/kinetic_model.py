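"""Monod-type batch kinetic model of a suspension CHO culture.

The model tracks six states — total and viable cell density plus the
concentrations of glucose, glutamine, lactate and ammonium — through a
batch cultivation.  Growth follows double-Monod kinetics on glucose and
glutamine, the specific death rate rises as glucose is depleted, substrate
uptake is Monod-type, and lactate/ammonium are produced with constant
yields.  Glutamine additionally decomposes abiotically to ammonium.

Units
-----
time          h
cell density  1e9 cells/L (numerically identical to 1e6 cells/mL)
concentration mM
uptake rates  mmol/(1e9 cells * h)

With these units the mass balances need no conversion factors:
``dc/dt = -q * Xv`` is directly in mM/h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CultureState",
    "KineticParameters",
    "FreeParameterSpec",
    "Trajectory",
    "SpecificRates",
    "SimulationError",
    "specific_rates",
    "ode_rhs",
    "simulate_batch",
    "STATE_NAMES",
    "DEFAULT_FREE_PARAMETERS",
]

logger = logging.getLogger(__name__)

STATE_NAMES = ("Xt", "Xv", "cGlc", "cGln", "cLac", "cAmm")

#: Parameters re-estimated by default during model updating.
DEFAULT_FREE_PARAMETERS = (
    "mu_max",
    "k_Glc",
    "k_Gln",
    "K_Glc",
    "K_Gln",
    "Y_LacGlc",
    "Y_AmmGln",
)


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failure time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class CultureState:
    """Culture state at one point in time.

    Attributes
    ----------
    Xt, Xv
        Total and viable cell density [1e9 cells/L].
    cGlc, cGln, cLac, cAmm
        Glucose, glutamine, lactate and ammonium concentration [mM].
    """

    Xt: float
    Xv: float
    cGlc: float
    cGln: float
    cLac: float
    cAmm: float

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be finite and >= 0, got {v}")
        if self.Xv > self.Xt * (1 + 1e-9):
            raise ValueError(f"Xv ({self.Xv}) must not exceed Xt ({self.Xt})")

    @property
    def viability(self) -> float:
        """Viability in percent, 100 * Xv / Xt (0 for an empty culture)."""
        if self.Xt == 0:
            return 0.0
        return 100.0 * self.Xv / self.Xt

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CultureState":
        return cls(**dict(zip(STATE_NAMES, map(float, y))))


PARAMETER_NAMES = (
    "mu_max",
    "mu_d_max",
    "mu_d_min",
    "K_Glc",
    "K_Gln",
    "k_Glc",
    "k_Gln",
    "q_Glc_max",
    "q_Gln_max",
    "Y_LacGlc",
    "Y_AmmGln",
    "k_lys",
    "k_Gln_decomp",
    "K_d_Glc",
)


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the batch kinetics.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate [1/h].
    mu_d_max, mu_d_min : float
        Maximum and minimum specific death rate [1/h]; the death rate
        approaches ``mu_d_min + mu_d_max`` as glucose is exhausted.
    K_Glc, K_Gln : float
        Monod constants of the growth rate [mM].
    k_Glc, k_Gln : float
        Monod constants of substrate uptake [mM].
    q_Glc_max, q_Gln_max : float
        Maximum specific uptake rates [mmol/(1e9 cells h)].
    Y_LacGlc, Y_AmmGln : float
        Yields of lactate per glucose and ammonium per glutamine [mol/mol].
    k_lys : float
        First-order lysis rate of dead cells [1/h].
    k_Gln_decomp : float
        Abiotic glutamine decomposition rate [1/h].
    K_d_Glc : float
        Glucose half-saturation of the death term [mM].
    """

    mu_max: float
    mu_d_max: float
    mu_d_min: float
    K_Glc: float
    K_Gln: float
    k_Glc: float
    k_Gln: float
    q_Glc_max: float
    q_Gln_max: float
    Y_LacGlc: float
    Y_AmmGln: float
    k_lys: float
    k_Gln_decomp: float
    K_d_Glc: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        if self.mu_d_min > self.mu_d_max:
            raise ValueError("mu_d_min must not exceed mu_d_max")

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAMETER_NAMES}

    def with_values(self, **updates: float) -> "KineticParameters":
        return replace(self, **updates)

    def free_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


@dataclass(frozen=True)
class FreeParameterSpec:
    """Ordered free-parameter names with elementwise box bounds.

    The default convention places the bounds at the prior value +/- 50%,
    mirroring how estimation boundaries are commonly set from the
    coefficients of variation of an earlier small-scale study.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if not (len(self.names) == lo.size == up.size):
            raise ValueError("names, lower and upper must have equal length")
        if np.any(lo >= up):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def n_p(self) -> int:
        return len(self.names)

    @classmethod
    def from_prior(
        cls,
        prior: KineticParameters,
        names: Sequence[str] = DEFAULT_FREE_PARAMETERS,
        fraction: float = 0.5,
    ) -> "FreeParameterSpec":
        """Bounds at prior +/- ``fraction`` (default +/-50%) around each value."""
        p0 = prior.free_vector(names)
        if np.any(p0 <= 0):
            raise ValueError("relative bounds require strictly positive prior values")
        return cls(tuple(names), p0 * (1 - fraction), p0 * (1 + fraction))

    def clip(self, p: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(p, dtype=float), self.lower, self.upper)


class SpecificRates(NamedTuple):
    mu: float
    mu_d: float
    qGlc: float
    qGln: float
    qLac: float
    qAmm: float


def specific_rates(state: CultureState, p: KineticParameters) -> SpecificRates:
    """Algebraic rate laws evaluated at one culture state.

    Growth is double-Monod in glucose and glutamine; the death rate rises
    from ``mu_d_min`` toward ``mu_d_min + mu_d_max`` as glucose runs out;
    uptake is Monod-type; lactate and ammonium production are coupled to
    uptake through constant yields.
    """
    mu, mu_d, qGlc, qGln, qLac, qAmm = _rates_from_arrays(state.to_array(), _ptuple(p))
    return SpecificRates(mu, mu_d, qGlc, qGln, qLac, qAmm)


def ode_rhs(state: CultureState, p: KineticParameters) -> np.ndarray:
    """Time derivative of the six states at one state point.

    ``dXv/dt = (mu - mu_d) Xv``; dead cells (Xt - Xv) lyse with rate
    ``k_lys``; substrate balances are uptake times viable density, with
    abiotic glutamine decomposition feeding ammonium.
    """
    return _rhs(0.0, state.to_array(), _ptuple(p))


def _ptuple(p: KineticParameters) -> tuple[float, ...]:
    return tuple(getattr(p, n) for n in PARAMETER_NAMES)


def _rates_from_arrays(y: np.ndarray, pt: tuple[float, ...]):
    (mu_max, mu_d_max, mu_d_min, K_Glc, K_Gln, k_Glc, k_Gln,
     q_Glc_max, q_Gln_max, Y_LacGlc, Y_AmmGln, _k_lys, _k_dec, K_d_Glc) = pt
    cGlc = max(y[2], 0.0)
    cGln = max(y[3], 0.0)
    mu = mu_max * cGlc / (cGlc + K_Glc) * cGln / (cGln + K_Gln)
    mu_d = mu_d_min + mu_d_max * K_d_Glc / (cGlc + K_d_Glc)
    qGlc = q_Glc_max * cGlc / (cGlc + k_Glc)
    qGln = q_Gln_max * cGln / (cGln + k_Gln)
    return mu, mu_d, qGlc, qGln, Y_LacGlc * qGlc, Y_AmmGln * qGln


def _rhs(t: float, y: np.ndarray, pt: tuple[float, ...]) -> np.ndarray:
    mu, mu_d, qGlc, qGln, qLac, qAmm = _rates_from_arrays(y, pt)
    k_lys = pt[11]
    k_dec = pt[12]
    Xt, Xv = y[0], y[1]
    cGln = max(y[3], 0.0)
    return np.array(
        [
            mu * Xv - k_lys * max(Xt - Xv, 0.0),
            (mu - mu_d) * Xv,
            -qGlc * Xv,
            -qGln * Xv - k_dec * cGln,
            qLac * Xv,
            qAmm * Xv + k_dec * cGln,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 6), column order = STATE_NAMES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if s.shape != (t.size, 6):
            raise ValueError("states must have shape (n_times, 6)")

    def column(self, name: str) -> np.ndarray:
        if name == "Via":
            return self.viability
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def viability(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            via = 100.0 * self.states[:, 1] / self.states[:, 0]
        return np.where(self.states[:, 0] > 0, via, 0.0)

    def final_state(self) -> CultureState:
        return CultureState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df.insert(3, "Via", self.viability)
        return df


def simulate_batch(
    init: CultureState,
    p: KineticParameters,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the batch kinetics and return states on ``times``.

    ``times[0]`` is the inoculation time; the returned trajectory starts
    exactly at ``init``.  Uses an adaptive, stiffness-capable solver.
    Small negative undershoots near depleted substrates are clipped to
    zero (logged at debug level).

    Raises
    ------
    SimulationError
        If the integrator breaks down; the exception carries the last
        time reached.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing grid of length >= 2")
    pt = _ptuple(p)
    sol = solve_ivp(
        _rhs,
        (t[0], t[-1]),
        init.to_array(),
        t_eval=t,
        args=(pt,),
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        reached = float(sol.t[-1]) if sol.t.size else float(t[0])
        raise SimulationError(
            f"ODE integration failed at t = {reached:.3f} h: {sol.message}", time=reached
        )
    states = sol.y.T.copy()
    if np.any(states < 0):
        worst = states.min()
        if worst < -1e-6:
            logger.warning("clipping negative states (min %.3e) to zero", worst)
        else:
            logger.debug("clipping tiny negative undershoot (min %.3e) to zero", worst)
        states = np.clip(states, 0.0, None)
    # keep viability well-defined: Xv may not exceed Xt
    states[:, 1] = np.minimum(states[:, 1], states[:, 0])
    states[0] = init.to_array()
    return Trajectory(t, states)
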