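"""Core production-utility equations of the fatigue models.

Everything here is a pure, stateless computation.  The behavioural story:
an ACT-R-style production system repeatedly resolves a conflict among the
productions that match the current task state (waiting, attending,
responding).  Each production carries a utility value that is degraded by
accumulated microlapses and, depending on the model variant, either by
time-on-task (CMF) or modulated by a gamma-power-derived motivation value
zeta (gamma models).  A conflict-resolution cycle ends in a *microlapse*
when no production's noise-perturbed utility clears the utility threshold.

Model variants
--------------
``cmf``     utility  U(t) = upsilon * lambda**N_ml * (1 + t)**rho
            threshold UT(t) = tau * (1 + t)**kappa          (t in minutes)
``gamma1``  utility  U = upsilon * lambda**N_ml * zeta, zeta from 2-min
            binned gamma power; threshold fixed at tau
``gamma2``  same as gamma1 but zeta computed per trial
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MICROLAPSE",
    "ParameterError",
    "ModelParams",
    "FatigueState",
    "SelectionContext",
    "cmf_utility",
    "cmf_threshold",
    "gamma_utility",
    "sample_utility_noise",
    "selection_probabilities",
    "resolve_conflict",
]

#: Sentinel returned by :func:`resolve_conflict` when no production fires.
MICROLAPSE = -1

VARIANTS = ("cmf", "gamma1", "gamma2")


class ParameterError(ValueError):
    """A model parameter violated its documented bound."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class ModelParams:
    """All free and fixed parameters of one model variant.

    Parameters
    ----------
    variant
        One of ``cmf``, ``gamma1``, ``gamma2``.
    upsilon
        Initial production utility value, > 0 (unitless).
    lambda_ml
        Microlapse penalty factor in (0, 1]; each microlapse multiplies the
        utility by this factor.
    phi
        Conflict-resolution cycle time in seconds, in (0.01, 0.1).
    tau
        Initial utility threshold, fixed at 2.0 by convention.
    rho
        Utility time-on-task exponent in (-1, 0]; CMF only (None for gamma
        variants, treated as 0).
    kappa
        Threshold time-on-task exponent in (-1, 0]; CMF only.
    s
        Logistic utility-noise scale, >= 0 (unitless).
    t_microlapse
        Extra processing-time penalty per microlapse, seconds.
    t_motor
        Motor execution time added to every keypress, seconds.
    mismatch_penalty
        Additive utility penalty applied by the simulator to productions
        that do not match the current task state (e.g. "respond" before the
        stimulus).  Keeps state-inappropriate firings rare without giving
        productions separate utilities.
    """

    variant: str
    upsilon: float
    lambda_ml: float
    phi: float
    tau: float = 2.0
    rho: float | None = None
    kappa: float | None = None
    s: float = 0.45
    t_microlapse: float = 0.050
    t_motor: float = 0.100
    mismatch_penalty: float = 10.0

    def __post_init__(self) -> None:
        _check(self.variant in VARIANTS, f"unknown variant {self.variant!r}")
        _check(self.upsilon > 0.0, f"upsilon must be > 0, got {self.upsilon}")
        _check(
            0.0 < self.lambda_ml <= 1.0,
            f"lambda_ml must be in (0, 1], got {self.lambda_ml}",
        )
        _check(0.01 < self.phi < 0.1, f"phi must be in (0.01, 0.1) s, got {self.phi}")
        _check(self.tau > 0.0, f"tau must be > 0, got {self.tau}")
        _check(self.s >= 0.0, f"noise scale s must be >= 0, got {self.s}")
        _check(self.t_microlapse >= 0.0, "t_microlapse must be >= 0")
        _check(self.t_motor >= 0.0, "t_motor must be >= 0")
        if self.variant == "cmf":
            rho = 0.0 if self.rho is None else self.rho
            kappa = 0.0 if self.kappa is None else self.kappa
            _check(-1.0 < rho <= 0.0, f"rho must be in (-1, 0], got {rho}")
            _check(-1.0 < kappa <= 0.0, f"kappa must be in (-1, 0], got {kappa}")
        else:
            _check(
                self.rho is None and self.kappa is None,
                "rho/kappa are CMF-only parameters; gamma variants fix them at 0",
            )

    @property
    def rho_eff(self) -> float:
        return 0.0 if self.rho is None else self.rho

    @property
    def kappa_eff(self) -> float:
        return 0.0 if self.kappa is None else self.kappa

    @property
    def n_free(self) -> int:
        """Free-parameter count used in AIC (upsilon, lambda, phi [, rho, kappa])."""
        return 5 if self.variant == "cmf" else 3


@dataclass
class FatigueState:
    """Running fatigue bookkeeping for one session.

    ``n_ml`` is the session-cumulative microlapse count; ``t`` is
    time-on-task in minutes.  Both are non-decreasing within a session.
    The utility equations are fed the *within-phase* microlapse count kept
    by the simulator; this state records the session totals.
    """

    n_ml: int = 0
    t: float = 0.0

    def advance(self, minutes: float) -> None:
        _check(minutes >= 0.0, "time-on-task cannot decrease")
        self.t += minutes

    def record_microlapses(self, count: int) -> None:
        _check(count >= 0, "microlapse count cannot decrease")
        self.n_ml += count


@dataclass(frozen=True)
class SelectionContext:
    """Candidate productions competing in one conflict-resolution cycle."""

    utilities: Sequence[float]
    threshold: float
    s: float

    def __post_init__(self) -> None:
        _check(len(self.utilities) > 0, "candidate set must be non-empty")
        _check(self.s >= 0.0, "noise scale s must be >= 0")

    @property
    def above_threshold(self) -> np.ndarray:
        """Indices of candidates whose noiseless utility clears the threshold."""
        u = np.asarray(self.utilities, dtype=float)
        return np.flatnonzero(u >= self.threshold)


def cmf_utility(
    upsilon: float, lambda_ml: float, n_ml: int, t_minutes: float, rho: float
) -> float:
    """Time-on-task/microlapse-moderated utility: upsilon * lambda**N * (1+t)**rho."""
    _check(upsilon > 0.0, f"upsilon must be > 0, got {upsilon}")
    _check(0.0 < lambda_ml <= 1.0, f"lambda_ml must be in (0, 1], got {lambda_ml}")
    _check(n_ml >= 0 and float(n_ml).is_integer(), f"n_ml must be a non-negative integer, got {n_ml}")
    _check(t_minutes >= 0.0, f"t_minutes must be >= 0, got {t_minutes}")
    return upsilon * (lambda_ml ** n_ml) * (1.0 + t_minutes) ** rho


def cmf_threshold(tau: float, t_minutes: float, kappa: float) -> float:
    """Time-on-task-moderated utility threshold: tau * (1+t)**kappa."""
    _check(tau > 0.0, f"tau must be > 0, got {tau}")
    _check(t_minutes >= 0.0, f"t_minutes must be >= 0, got {t_minutes}")
    return tau * (1.0 + t_minutes) ** kappa


def gamma_utility(upsilon: float, lambda_ml: float, n_ml: int, zeta: float) -> float:
    """Motivation-moderated utility: upsilon * lambda**N * zeta (zeta >= 0)."""
    _check(upsilon > 0.0, f"upsilon must be > 0, got {upsilon}")
    _check(0.0 < lambda_ml <= 1.0, f"lambda_ml must be in (0, 1], got {lambda_ml}")
    _check(n_ml >= 0 and float(n_ml).is_integer(), f"n_ml must be a non-negative integer, got {n_ml}")
    _check(zeta >= 0.0, f"zeta cannot go below zero, got {zeta}")
    return upsilon * (lambda_ml ** n_ml) * zeta


def moderated_utility(
    params: ModelParams, n_ml: int, t_minutes: float, zeta: float = 1.0
) -> float:
    """Variant-dispatching utility (CMF ignores zeta; gamma variants ignore t)."""
    if params.variant == "cmf":
        return cmf_utility(params.upsilon, params.lambda_ml, n_ml, t_minutes, params.rho_eff)
    return gamma_utility(params.upsilon, params.lambda_ml, n_ml, zeta)


def moderated_threshold(params: ModelParams, t_minutes: float) -> float:
    """Variant-dispatching threshold (constant tau for gamma variants)."""
    if params.variant == "cmf":
        return cmf_threshold(params.tau, t_minutes, params.kappa_eff)
    return params.tau


def sample_utility_noise(s: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n logistic noise values with mean 0 and scale s (variance pi^2 s^2 / 3)."""
    _check(s >= 0.0, f"noise scale s must be >= 0, got {s}")
    _check(n >= 1, f"n must be >= 1, got {n}")
    if s == 0.0:
        return np.zeros(n)
    return rng.logistic(loc=0.0, scale=s, size=n)


def _logistic_cdf(x: np.ndarray | float) -> np.ndarray | float:
    # F(x) = 1 / (1 + e^-x); for s = 0 callers pass +-inf and get the step function
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))


def microlapse_probability(context: SelectionContext) -> float:
    """Probability that every candidate's noisy utility falls below threshold.

    Equals the product over candidates of F((UT - U_j) / s) with F the
    logistic CDF; at s = 0 it is a product of indicators.
    """
    u = np.asarray(context.utilities, dtype=float)
    if context.s == 0.0:
        return float(np.all(u < context.threshold))
    z = (context.threshold - u) / context.s
    return float(np.prod(_logistic_cdf(z)))


def selection_probabilities(context: SelectionContext) -> tuple[np.ndarray, float]:
    """Closed-form selection law over the above-threshold set J.

    Returns ``(probs, p_microlapse)`` where ``probs`` has one entry per
    candidate: soft-max exp(U_i / 2s) / sum_J exp(U_j / 2s) for members of
    J = {j : U_j >= UT}, zero elsewhere.  ``p_microlapse`` is the product
    of per-candidate logistic CDFs (1 if J is empty and s = 0 semantics
    degenerate to the indicator product).  At s = 0 with tied maximal
    utilities the lowest candidate index takes all mass (flagged with a
    warning).
    """
    u = np.asarray(context.utilities, dtype=float)
    J = context.above_threshold
    probs = np.zeros_like(u)
    if J.size == 0:
        return probs, 1.0
    p_ml = microlapse_probability(context)
    if context.s == 0.0:
        uj = u[J]
        top = J[uj == uj.max()]
        if top.size > 1:
            warnings.warn(
                "s = 0 with tied maximal utilities; breaking tie by lowest index",
                stacklevel=2,
            )
        probs[top[0]] = 1.0
        return probs, p_ml
    z = u[J] / (2.0 * context.s)
    w = np.exp(z - z.max())
    probs[J] = w / w.sum()
    return probs, p_ml


def resolve_conflict(context: SelectionContext, rng: np.random.Generator) -> int:
    """Run one conflict-resolution cycle; return fired index or MICROLAPSE.

    Mechanism (sampling the model's two closed-form laws directly):

    1. every candidate receives an independent logistic(s) noise draw and
       is checked against the threshold; if *no* candidate passes, the
       cycle is a microlapse — this event has probability exactly
       prod_j F((UT - U_j)/s);
    2. otherwise one production fires, drawn from the Luce soft-max
       exp(U_i / 2s) over all candidates.  When every candidate clears the
       threshold this coincides exactly with the closed form of
       :func:`selection_probabilities`; sub-threshold candidates retain the
       vanishing soft-max mass the noise grants them, which is what lets a
       mismatching production (e.g. "respond" before the stimulus) fire on
       rare cycles.
    """
    u = np.asarray(context.utilities, dtype=float)
    s = context.s
    if s == 0.0:
        if np.all(u < context.threshold):
            return MICROLAPSE
        top = np.flatnonzero(u == u.max())
        if top.size > 1:
            warnings.warn(
                "s = 0 with tied maximal utilities; breaking tie by lowest index",
                stacklevel=2,
            )
        return int(top[0])
    noise = sample_utility_noise(s, u.size, rng)
    if np.all(u + noise < context.threshold):
        return MICROLAPSE
    z = u / (2.0 * s)
    w = np.exp(z - z.max())
    return int(rng.choice(u.size, p=w / w.sum()))
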