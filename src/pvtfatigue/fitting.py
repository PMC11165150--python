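"""Per-subject fitting by simulated likelihood with DE-MCMC, plus AIC.

The trial-level likelihood has no closed form, so it is approximated by
forward simulation: at a proposed parameter vector the response process is
simulated many times under each observed trial's conditions (time-on-task
and motivation zeta), a defective mixture is formed — point masses for the
false-start and sleep-attack categories plus a continuous density over
RTs — and the observed trials are scored against it.  Because the
microlapse moderator resets at stimulus onset, trials are conditionally
independent given (t, zeta) and the likelihood factorises over trials.

Sampling uses differential-evolution MCMC: each chain proposes
theta_k + gamma_DE * (theta_r1 - theta_r2) + jitter, reflecting off the
parameter bounds, with uniform priors on those bounds.  A fresh simulation
seed is derived from (root seed, chain, iteration) for every proposal, so
the stochastic likelihood surface is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import ModelParams, ParameterError, _check
from .simulator import TaskConfig

__all__ = [
    "ParameterBounds",
    "LikelihoodConfig",
    "DESettings",
    "FitResult",
    "FitError",
    "approx_loglik",
    "simulate_response_rts",
    "fit_subject",
    "aic",
    "compare_models",
    "default_bounds",
]

FREE_PARAMS = {
    "cmf": ("upsilon", "lambda_ml", "phi", "rho", "kappa"),
    "gamma1": ("upsilon", "lambda_ml", "phi"),
    "gamma2": ("upsilon", "lambda_ml", "phi"),
}

# Practical prior boxes: the initial-utility bound is (0, inf) in principle;
# the uniform prior needs a finite box, and 20 is far above any plausible
# utility given the fixed threshold of 2.
_EPS = 1e-6
_DEFAULT_BOX = {
    "upsilon": (_EPS, 20.0),
    "lambda_ml": (_EPS, 1.0 - _EPS),
    "phi": (0.01 + _EPS, 0.1 - _EPS),
    "rho": (-1.0 + _EPS, 0.0 - _EPS),  # rho may not equal 0
    "kappa": (-1.0 + _EPS, 0.0),       # kappa may equal 0
}


class FitError(RuntimeError):
    """Fitting failed (persistent non-finite likelihood)."""


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) prior box for one model variant."""

    variant: str
    box: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {name: self.box.get(name, _DEFAULT_BOX[name]) for name in FREE_PARAMS[self.variant]}
        for name, (lo, hi) in merged.items():
            _check(lo < hi, f"bound for {name} must satisfy lower < upper")
        object.__setattr__(self, "box", merged)

    @property
    def names(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.variant]

    @property
    def d(self) -> int:
        return len(self.names)

    def lowers(self) -> np.ndarray:
        return np.array([self.box[n][0] for n in self.names])

    def uppers(self) -> np.ndarray:
        return np.array([self.box[n][1] for n in self.names])

    def to_params(self, theta: np.ndarray, **fixed) -> ModelParams:
        kw = dict(zip(self.names, map(float, theta)))
        if self.variant != "cmf":
            kw.pop("rho", None)
            kw.pop("kappa", None)
        return ModelParams(variant=self.variant, **kw, **fixed)


def default_bounds(variant: str) -> ParameterBounds:
    return ParameterBounds(variant=variant)


@dataclass(frozen=True)
class LikelihoodConfig:
    """Simulated-likelihood construction settings.

    ``n_sim`` simulated trials per proposal, shared across the observed
    trials' condition groups; density over RTs either a Gaussian KDE
    (default: robust with the few draws a per-trial condition receives,
    and well-behaved because the onset-phase jitter keeps the simulated
    RT distribution continuous) or a fixed histogram with 10 ms bins over
    150-1000 ms plus uniformly spread tail mass; ``epsilon`` floors every
    mass/density so no observation scores -inf.
    """

    n_sim: int = 2000
    density: str = "kde"
    epsilon: float = 1e-6
    hist_lo: float = 150.0
    hist_hi: float = 1000.0
    hist_bin: float = 10.0
    kde_bw: float = 15.0  # fixed bandwidth (ms); adaptive bandwidths reward
                          # proposals that concentrate all mass in one place

    def __post_init__(self) -> None:
        _check(self.n_sim >= 100, "n_sim must be >= 100")
        _check(self.epsilon > 0, "epsilon must be > 0")
        _check(self.density in ("kde", "histogram"), "density must be 'kde' or 'histogram'")


def _logistic_cdf(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))


try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    @_njit(cache=False)
    def _response_kernel(seed, t0, zeta, upsilon, lam, phi, tau, rho, kappa,
                         s, t_ml, t_motor, delta, timeout, is_cmf):
        np.random.seed(seed)
        n = t0.shape[0]
        rt = np.full(n, np.nan)
        p_wait = 1.0 / (1.0 + np.exp(min(delta / (2.0 * s), 700.0)))
        for i in range(n):
            # clock overshoot at onset: residual life of the straddling
            # pre-stimulus event (length-biased: microlapse events last
            # phi + t_ml and are hit proportionally more often)
            if is_cmf:
                u0 = upsilon * (1.0 + t0[i]) ** rho
                ut0 = tau * (1.0 + t0[i]) ** kappa
            else:
                u0 = upsilon * zeta[i]
                ut0 = tau
            x0 = min(max((ut0 - u0) / s, -700.0), 700.0)
            p0 = (1.0 / (1.0 + np.exp(-x0)))                 * (1.0 / (1.0 + np.exp(-min(x0 + delta / s, 700.0))))
            q_ml = p0 * (phi + t_ml) / ((1.0 - p0) * phi + p0 * (phi + t_ml))
            if np.random.random() < q_ml:
                clock = (phi + t_ml) * np.random.random()
            else:
                clock = phi * np.random.random()
            lam_pow = 1.0
            attending = True
            while clock < timeout:
                if is_cmf:
                    t_min = t0[i] + clock / 60.0
                    u = upsilon * lam_pow * (1.0 + t_min) ** rho
                    ut = tau * (1.0 + t_min) ** kappa
                else:
                    u = upsilon * lam_pow * zeta[i]
                    ut = tau
                x = (ut - u) / s
                if x > 700.0:
                    x = 700.0
                elif x < -700.0:
                    x = -700.0
                p_ml = 1.0 / (1.0 + np.exp(-x))
                if attending:
                    x2 = min(x + delta / s, 700.0)
                    p_ml *= 1.0 / (1.0 + np.exp(-x2))
                r = np.random.random()
                if r < p_ml:
                    clock += phi + t_ml
                    lam_pow *= lam
                else:
                    clock += phi
                    if attending:
                        if r <= 1.0 - p_wait:
                            attending = False
                        # else: mismatching wait wasted the cycle
                    else:
                        if clock + t_motor < timeout:
                            rt[i] = clock + t_motor
                        break
        return rt

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate_response_rts(
    params: ModelParams,
    t_onset_min: np.ndarray,
    zeta: np.ndarray,
    rng: np.random.Generator,
    task: TaskConfig | None = None,
) -> np.ndarray:
    """Vectorised response-phase simulation; one RT (seconds) per entry.

    Each entry simulates a trial whose stimulus appears at session time
    ``t_onset_min`` minutes with motivation ``zeta``; NaN marks a 30 s
    timeout (sleep attack).  The cycle mechanics mirror the scalar
    simulator: microlapse gate with probability prod F((UT - U_j)/s), a
    mismatching "wait" alternative during the attending stage, and a
    uniform(0, phi) clock offset standing in for the cycle overshoot at
    stimulus onset.
    """
    task = task or TaskConfig()
    n = t_onset_min.size
    s = params.s
    delta = params.mismatch_penalty
    is_cmf = params.variant == "cmf"
    if s > 0 and _HAVE_NUMBA:
        seed = int(rng.integers(0, 2**31 - 1))
        return _response_kernel(
            seed,
            np.ascontiguousarray(t_onset_min, dtype=np.float64),
            np.ascontiguousarray(np.broadcast_to(zeta, (n,)), dtype=np.float64),
            float(params.upsilon), float(params.lambda_ml), float(params.phi),
            float(params.tau), float(params.rho_eff), float(params.kappa_eff),
            float(s), float(params.t_microlapse), float(params.t_motor),
            float(delta), float(task.timeout_s), is_cmf,
        )
    p_wait = 1.0 / (1.0 + np.exp(min(delta / (2.0 * s), 700.0))) if s > 0 else 0.0

    rt = np.full(n, np.nan)
    # compact working arrays, compressed as trials finish
    idx = np.arange(n)
    # onset clock offset: residual life of the straddling pre-stimulus
    # event (length-biased between plain cycles and penalised microlapses)
    zeta_b = np.broadcast_to(zeta, (n,)).astype(float)
    if is_cmf:
        u0 = params.upsilon * (1.0 + t_onset_min) ** params.rho_eff
        ut0 = params.tau * (1.0 + t_onset_min) ** params.kappa_eff
    else:
        u0 = params.upsilon * zeta_b
        ut0 = params.tau
    if s > 0:
        x0 = (ut0 - u0) / s
        p0 = _logistic_cdf(x0) * _logistic_cdf(x0 + delta / s)
    else:
        p0 = (u0 < ut0).astype(float)
    long_ev = params.phi + params.t_microlapse
    q_ml = p0 * long_ev / ((1.0 - p0) * params.phi + p0 * long_ev)
    is_long = rng.random(n) < q_ml
    clock = np.where(is_long, long_ev, params.phi) * rng.random(n)
    lam_pow = np.ones(n)
    attending = np.ones(n, dtype=bool)
    t0 = t_onset_min.astype(float).copy()
    z = np.broadcast_to(zeta, (n,)).astype(float).copy()

    while idx.size:
        if is_cmf:
            t_min = t0 + clock / 60.0
            u = params.upsilon * lam_pow * (1.0 + t_min) ** params.rho_eff
            ut = params.tau * (1.0 + t_min) ** params.kappa_eff
        else:
            u = params.upsilon * lam_pow * z
            ut = params.tau
        if s > 0:
            x = (ut - u) / s
            p_ml = _logistic_cdf(x)
            p_ml[attending] *= _logistic_cdf(x[attending] + delta / s)
        else:
            p_ml = (u < ut).astype(float)
        draw = rng.random(idx.size)
        ml = draw < p_ml
        fired_wait = (~ml) & attending & (draw > 1.0 - p_wait)
        clock += params.phi + params.t_microlapse * ml
        lam_pow[ml] *= params.lambda_ml
        progress = (~ml) & (~fired_wait)
        finish = progress & (~attending)
        rt[idx[finish]] = clock[finish] + params.t_motor
        attending &= ~progress
        # a trial whose firing probability has collapsed (or whose clock ran
        # out) can only microlapse its way to the 30 s deadline: call it now
        hopeless = (clock >= task.timeout_s) | (p_ml > 1.0 - 1e-5)
        keep = ~(finish | hopeless)
        if not keep.all():
            idx = idx[keep]
            clock = clock[keep]
            lam_pow = lam_pow[keep]
            attending = attending[keep]
            t0 = t0[keep]
            z = z[keep]
    rt[rt >= task.timeout_s] = np.nan  # presses beyond the deadline count as timeouts
    return rt


def _false_start_mass(params: ModelParams, t_onset_min: np.ndarray, zeta: np.ndarray,
                      task: TaskConfig) -> np.ndarray:
    """Closed-form probability that "respond" fires during a mean-length ISI."""
    s = params.s
    if s == 0:
        return np.zeros(np.shape(t_onset_min))
    if params.variant == "cmf":
        u = params.upsilon * (1.0 + t_onset_min) ** params.rho_eff
        ut = params.tau * (1.0 + t_onset_min) ** params.kappa_eff
    else:
        u = params.upsilon * zeta
        ut = params.tau
    p_ml = _logistic_cdf((ut - u) / s) * _logistic_cdf((ut - u + params.mismatch_penalty) / s)
    p_resp = 1.0 / (1.0 + math.exp(min(params.mismatch_penalty / (2.0 * s), 700.0)))
    q_cycle = np.minimum((1.0 - p_ml) * p_resp, 1.0)
    n_cycles = float(np.mean(task.isi_values)) / params.phi
    return 1.0 - (1.0 - q_cycle) ** n_cycles


class _LikelihoodData:
    """Pre-grouped observation structure, built once per subject.

    Trials sharing a motivation/time condition share one simulated RT
    distribution: CMF and gamma-1 trials group by 2-minute bin (zeta is
    constant within a bin), gamma-2 trials are their own conditions.
    """

    def __init__(self, observed: pd.DataFrame, variant: str):
        _check(len(observed) >= 1, "observed session must contain at least one trial")
        df = observed.copy()
        if "zeta" not in df.columns or variant == "cmf":
            df["zeta"] = 1.0
        df["t_onset_min"] = df["onset_s"] / 60.0
        if variant == "gamma2":
            # gamma-variant conditions depend only on zeta, so trials pool
            # into zeta-quantile bins: each condition then receives enough
            # simulated draws to resolve the small microlapse-bump masses.
            # The (zeta, onset) sort makes grouping order-invariant.
            n = len(df)
            n_bins = min(12, n)
            order = np.lexsort((df["onset_s"].to_numpy(), df["zeta"].to_numpy()))
            rank = np.empty(n, dtype=int)
            rank[order] = np.arange(n)
            key = (rank * n_bins) // n
        else:
            key = np.minimum(df["onset_s"].to_numpy() // 120.0, 4).astype(int)
        uniq, inv = np.unique(key, return_inverse=True)
        self.n_groups = uniq.size
        self.g_t = np.zeros(self.n_groups)
        self.g_z = np.zeros(self.n_groups)
        np.add.at(self.g_t, inv, df["t_onset_min"].to_numpy())
        np.add.at(self.g_z, inv, df["zeta"].to_numpy())
        counts = np.bincount(inv, minlength=self.n_groups)
        self.g_t /= counts
        self.g_z /= counts
        # member conditions per group, in canonical order: simulated draws
        # cycle through these so a pooled group's density is the mixture
        # over its members' exact conditions (no mean-condition blur)
        t_arr = df["t_onset_min"].to_numpy()
        z_arr = df["zeta"].to_numpy()
        self.members = []
        for g in range(self.n_groups):
            idx = np.flatnonzero(inv == g)
            srt = idx[np.lexsort((t_arr[idx], z_arr[idx]))]
            self.members.append((t_arr[srt].copy(), z_arr[srt].copy()))
        types = df["response"].to_numpy()
        self.is_fs = types == "false_start"
        self.is_sleep = types == "sleep_attack"
        self.is_rt = ~(self.is_fs | self.is_sleep)
        self.obs_group = inv
        self.obs_rt = df["rt_ms"].to_numpy(dtype=float)


def _score(data: _LikelihoodData, params: ModelParams, config: LikelihoodConfig,
           rng: np.random.Generator, task: TaskConfig) -> float:
    task_timeout_ms = task.timeout_s * 1000.0
    reps = max(10, config.n_sim // data.n_groups)
    t_all = np.empty(data.n_groups * reps)
    z_all = np.empty(data.n_groups * reps)
    for g, (mt, mz) in enumerate(data.members):
        sl = slice(g * reps, (g + 1) * reps)
        t_all[sl] = np.resize(mt, reps)
        z_all[sl] = np.resize(mz, reps)
    sim_rt = simulate_response_rts(params, t_all, z_all, rng, task)         .reshape(data.n_groups, reps) * 1000.0  # ms

    eps = config.epsilon
    finite = np.isfinite(sim_rt)
    n_finite = finite.sum(axis=1)
    p_sleep = 1.0 - n_finite / reps
    p_fs = _false_start_mass(params, data.g_t, data.g_z, task)
    cont = np.maximum(1.0 - p_fs - p_sleep, 0.0)

    total = float(np.log(p_fs[data.obs_group[data.is_fs]] + eps).sum())
    total += float(np.log(p_sleep[data.obs_group[data.is_sleep]] + eps).sum())

    gi = data.obs_group[data.is_rt]
    rt_obs = data.obs_rt[data.is_rt]
    if gi.size:
        draws = sim_rt[gi]  # (n_obs, reps), NaN for timeouts
        if config.density == "kde":
            # fixed-bandwidth KDE over the fast region; responses slower than
            # hist_hi are scored by tail mass spread to the timeout, which is
            # what carries the cascade (deep-lapse) signal
            hi = config.hist_hi
            h = config.kde_bw
            below = np.nan_to_num(draws < hi)
            m_below = below.sum(axis=1)
            m_above = n_finite[gi] - m_below
            tail_width = max(task_timeout_ms - hi, config.hist_bin)
            z = (rt_obs[:, None] - np.where(np.isnan(draws) | (draws >= hi),
                                            np.inf, draws)) / h
            with np.errstate(invalid="ignore"):
                kern = np.exp(-0.5 * z * z)
            kern = np.nan_to_num(kern)
            m = np.maximum(n_finite[gi], 1)
            dens_fast = kern.sum(axis=1) / (m * h * math.sqrt(2.0 * math.pi))
            dens_tail = (m_above / m) / tail_width
            dens = np.where(rt_obs >= hi, dens_tail, dens_fast)
            dens[n_finite[gi] == 0] = 0.0
        else:
            # NaN draws compare False everywhere, so counts cover finite draws only
            lo, hi, w = config.hist_lo, config.hist_hi, config.hist_bin
            edge = lo + w * np.floor((rt_obs - lo) / w)
            in_lo = rt_obs < lo
            in_hi = rt_obs >= hi
            count = ((draws >= edge[:, None]) & (draws < edge[:, None] + w)).sum(axis=1)
            count = np.where(in_lo, (draws < lo).sum(axis=1), count)
            count = np.where(in_hi, (draws >= hi).sum(axis=1), count)
            hi_width = max(task_timeout_ms - hi, w)
            width = np.where(in_lo, lo, np.where(in_hi, hi_width, w))
            dens = count / np.maximum(n_finite[gi], 1) / width
        total += float(np.log(cont[gi] * dens + eps).sum())
    return total


def approx_loglik(
    observed: pd.DataFrame,
    params: ModelParams,
    config: LikelihoodConfig | None = None,
    rng: np.random.Generator | None = None,
    task: TaskConfig | None = None,
) -> float:
    """Simulated log-likelihood of one subject's trial table.

    ``observed`` needs columns onset_s, rt_ms, response (and zeta for the
    gamma variants).  Deterministic given the generator state.
    """
    config = config or LikelihoodConfig()
    task = task or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    data = _LikelihoodData(observed, params.variant)
    return _score(data, params, config, rng, task)


@dataclass(frozen=True)
class DESettings:
    """Differential-evolution MCMC settings (defaults scale with dimension d)."""

    n_chains: int | None = None  # default 4 * d
    n_iter: int = 1000
    burn: int = 500
    gamma_de: float | None = None  # default 2.38 / sqrt(2 d)
    jitter: float = 1e-4

    def resolved(self, d: int) -> tuple[int, int, int, float, float]:
        n_chains = self.n_chains if self.n_chains is not None else 4 * d
        gamma_de = self.gamma_de if self.gamma_de is not None else 2.38 / math.sqrt(2.0 * d)
        _check(n_chains >= 4, "DE-MCMC needs at least 4 chains")
        _check(0 <= self.burn < self.n_iter, "burn-in must be inside the iteration budget")
        return n_chains, self.n_iter, self.burn, gamma_de, self.jitter


@dataclass
class FitResult:
    """Posterior-mode estimates and fit indices for one subject/variant."""

    subject: str
    variant: str
    estimates: dict[str, float]
    neg2ll: float
    aic: float
    n_free: int
    n_iter: int
    n_chains: int
    acceptance_rate: float
    seed: int
    map_estimate: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "variant": self.variant,
            "estimates": self.estimates,
            "map_estimate": self.map_estimate,
            "neg2ll": self.neg2ll,
            "aic": self.aic,
            "n_free": self.n_free,
            "n_iter": self.n_iter,
            "n_chains": self.n_chains,
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
        }


def _reflect(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    y = np.mod(theta - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _eval_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def aic(neg2ll: float, n_free_params: int) -> float:
    """Akaike information criterion: -2LL + 2p."""
    _check(n_free_params >= 1, "n_free_params must be >= 1")
    return neg2ll + 2.0 * n_free_params


def fit_subject(
    observed: pd.DataFrame,
    variant: str,
    bounds: ParameterBounds | None = None,
    de: DESettings | None = None,
    lik: LikelihoodConfig | None = None,
    seed: int = 0,
    subject: str | None = None,
    task: TaskConfig | None = None,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """DE-MCMC fit of one subject's session under one model variant.

    The point estimate is the post-burn-in posterior mean under the
    uniform bounded prior (robust to the stochastic likelihood; the
    best-scoring sampled vector is kept as ``map_estimate``); its -2LL is
    re-evaluated with a dedicated seed and a doubled simulation count, and
    AIC = -2LL + 2p.  Fully reproducible given ``seed``.
    """
    bounds = bounds or default_bounds(variant)
    de = de or DESettings()
    lik = lik or LikelihoodConfig()
    task = task or TaskConfig()
    fixed = dict(fixed or {})
    d = bounds.d
    n_chains, n_iter, burn, gamma_de, jitter = de.resolved(d)
    lo, hi = bounds.lowers(), bounds.uppers()
    subject = subject if subject is not None else str(observed["subject"].iloc[0]) \
        if "subject" in observed.columns else "subject"

    data = _LikelihoodData(observed, variant)

    def loglik(theta: np.ndarray, rng: np.random.Generator,
               n_sim: int | None = None) -> float:
        cfg = lik if n_sim is None else LikelihoodConfig(
            n_sim=n_sim, density=lik.density, epsilon=lik.epsilon,
            hist_lo=lik.hist_lo, hist_hi=lik.hist_hi, hist_bin=lik.hist_bin,
            kde_bw=lik.kde_bw,
        )
        params = bounds.to_params(theta, **fixed)
        return _score(data, params, cfg, rng, task)

    # initialise chains at the best points of a Latin-hypercube pre-scan so
    # the short DE run starts near the high-likelihood region; half the scan
    # points pin phi at the value implied by the fastest observed response
    # (RT floor = 2 phi + t_motor), which is where phi is identified
    init_rng = _eval_rng(seed, 0)
    n_scan = 8 * n_chains
    grid = (init_rng.permuted(np.tile(np.arange(n_scan), (d, 1)), axis=1).T
            + init_rng.random((n_scan, d))) / n_scan
    scan = lo + (hi - lo) * grid
    if "phi" in bounds.names:
        rt_obs = data.obs_rt[data.is_rt]
        if rt_obs.size:
            t_motor = float(fixed.get("t_motor", 0.100))
            phi_hat = (np.nanmin(rt_obs) / 1000.0 - t_motor) / 2.0
            j_phi = bounds.names.index("phi")
            phi_hat = min(max(phi_hat, lo[j_phi]), hi[j_phi])
            scan[: n_scan // 2, j_phi] = phi_hat
    scan_ll = np.array([loglik(scan[j], _eval_rng(seed, 1, j)) for j in range(n_scan)])
    if not np.isfinite(scan_ll).any():
        raise FitError("persistent non-finite log-likelihood at initialisation")
    order = np.argsort(scan_ll)[::-1]
    theta = scan[order[:n_chains]].copy()
    cur_ll = scan_ll[order[:n_chains]].copy()
    bad = 0
    for k in range(n_chains):
        while not np.isfinite(cur_ll[k]):
            bad += 1
            if bad > n_chains * 10:
                raise FitError("persistent non-finite log-likelihood at initialisation")
            theta[k] = lo + (hi - lo) * init_rng.random(d)
            cur_ll[k] = loglik(theta[k], _eval_rng(seed, 1, k + n_chains * bad))

    best_ll = -np.inf
    best_theta = theta[0].copy()
    chain_sum = np.zeros((n_chains, d))
    chain_ll_sum = np.zeros(n_chains)
    chain_n = np.zeros(n_chains)
    n_accept = 0
    mh_rng = _eval_rng(seed, 2)
    for it in range(n_iter):
        for k in range(n_chains):
            # refresh the held likelihood on a fresh seed so chains cannot
            # stick to lucky realisations of the stochastic surface
            cur_ll[k] = loglik(theta[k], _eval_rng(seed, 5, it, k))
            r1, r2 = mh_rng.choice(np.delete(np.arange(n_chains), k), size=2, replace=False)
            # full-length difference moves every 10th iteration allow jumps
            # between separated modes (ter Braak's gamma = 1 recommendation)
            g = 1.0 if (it + 1) % 10 == 0 else gamma_de
            prop = theta[k] + g * (theta[r1] - theta[r2]) \
                + mh_rng.uniform(-jitter, jitter, size=d)
            prop = _reflect(prop, lo, hi)
            prop_ll = loglik(prop, _eval_rng(seed, 3, it, k))
            if np.isfinite(prop_ll) and math.log(mh_rng.random() + 1e-300) < prop_ll - cur_ll[k]:
                theta[k] = prop
                cur_ll[k] = prop_ll
                n_accept += 1
            if it >= burn:
                if np.isfinite(cur_ll[k]) and cur_ll[k] > best_ll:
                    best_ll = cur_ll[k]
                    best_theta = theta[k].copy()
                chain_sum[k] += theta[k]
                chain_ll_sum[k] += cur_ll[k]
                chain_n[k] += 1
        if it < burn and (it + 1) % 25 == 0:
            # outlier-chain handling (cf. DREAM): chains stranded far below
            # the population jump to the current best state
            q1, q3 = np.percentile(cur_ll, [25, 75])
            cutoff = q1 - 2.0 * (q3 - q1)
            stranded = np.flatnonzero(cur_ll < cutoff)
            if stranded.size:
                leader = int(np.argmax(cur_ll))
                for k_bad in stranded:
                    theta[k_bad] = theta[leader].copy()
                    cur_ll[k_bad] = cur_ll[leader]

    # posterior mean over converged chains only: a chain whose mean held
    # likelihood sits far below the best chain's never left a side plateau
    chain_mean_ll = chain_ll_sum / np.maximum(chain_n, 1)
    keep = chain_mean_ll >= chain_mean_ll.max() - 6.0
    post_mean = chain_sum[keep].sum(axis=0) / chain_n[keep].sum()

    # mode refinement: the point estimate is the maximiser of the seed-
    # averaged (common-random-numbers) simulated likelihood near the
    # converged-posterior mean — the posterior mode under the uniform prior
    from scipy.optimize import minimize

    refine_rngs = [5000 + j for j in range(5)]

    def smoothed_neg_ll(theta_raw: np.ndarray) -> float:
        th = _reflect(theta_raw, lo, hi)
        vals = [loglik(th, _eval_rng(seed, 6, j), n_sim=4 * lik.n_sim)
                for j in refine_rngs]
        return -float(np.mean(vals))

    starts = [post_mean, best_theta]
    best_opt = None
    for x0 in starts:
        opt = minimize(smoothed_neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 150, "xatol": 1e-4, "fatol": 0.05})
        if best_opt is None or opt.fun < best_opt.fun:
            best_opt = opt
    mode_theta = _reflect(best_opt.x, lo, hi)

    # final -2LL with a fixed draw count per condition so AICs are
    # comparable across variants with different condition granularity
    final_ll = loglik(mode_theta, _eval_rng(seed, 4), n_sim=256 * data.n_groups)
    neg2ll = -2.0 * final_ll
    estimates = dict(zip(bounds.names, map(float, mode_theta)))
    map_estimate = dict(zip(bounds.names, map(float, best_theta)))
    return FitResult(
        subject=subject,
        variant=variant,
        estimates=estimates,
        neg2ll=float(neg2ll),
        aic=float(aic(neg2ll, d)),
        n_free=d,
        n_iter=n_iter,
        n_chains=n_chains,
        acceptance_rate=n_accept / (n_iter * n_chains),
        seed=seed,
        map_estimate=map_estimate,
    )


def compare_models(fits: Mapping[str, Sequence[FitResult]]) -> tuple[pd.DataFrame, dict]:
    """Per-subject AIC comparison across >= 2 variants.

    Returns a table with one row per subject and one AIC column per
    variant plus pairwise-against-winner deltas, and a summary dict with
    per-variant mean AIC, the mean and SE of the pairwise AIC difference
    of the two best variants, and the winner (lowest mean AIC).
    """
    _check(len(fits) >= 2, "need fits for at least two variants")
    variants = list(fits)
    subj_sets = [tuple(sorted(f.subject for f in fits[v])) for v in variants]
    if len(set(subj_sets)) != 1:
        raise ParameterError("all variants must cover the same subjects")
    rows = {}
    for v in variants:
        for f in fits[v]:
            rows.setdefault(f.subject, {})[v] = f.aic
    table = pd.DataFrame.from_dict(rows, orient="index")[variants].sort_index()
    mean_aic = table.mean()
    winner = str(mean_aic.idxmin())
    runner = str(mean_aic.drop(winner).idxmin())
    diff = table[runner] - table[winner]
    n = len(table)
    summary = {
        "mean_aic": {v: float(mean_aic[v]) for v in variants},
        "winner": winner,
        "runner_up": runner,
        "delta_aic_mean": float(diff.mean()),
        "delta_aic_se": float(diff.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        "n_subjects": n,
    }
    for v in variants:
        table[f"delta_vs_{winner}_{v}"] = table[v] - table[winner]
    return table, summary
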