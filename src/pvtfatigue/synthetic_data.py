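"""Synthetic fixtures: gamma-power series, cohorts, and EEG epochs.

No public dataset accompanies the task this package models, so every
analysis and fitting path is exercised on synthetic data that emulates the
study conditions: 10-minute sessions with discrete 2-10 s ISIs, alert RTs
in the 150-500 ms band stretching rightward with time-on-task, and
per-trial high-gamma power with a non-monotonic bin-level trend (a dip in
the final 2-minute bin) plus trial-level lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .gamma_motivation import GammaSeries, ZetaConfig, zeta_binned, zeta_trial, per_trial_zeta
from .model_core import ModelParams, ParameterError, _check
from .neural_features import EpochMatrix
from .simulator import SessionResult, TaskConfig, simulate_session

__all__ = [
    "GammaTrendSpec",
    "generate_gamma_series",
    "generate_synthetic_cohort",
    "generate_synthetic_epochs",
    "SyntheticCohort",
]


@dataclass(frozen=True)
class GammaTrendSpec:
    """Bin-level mean log-power profile with trial-level lognormal noise.

    The default profile is non-monotonic with its trough in bin 5 and
    local peaks in bins 2 and 4, echoing the shape of observed binned
    high-gamma power; ``sigma`` is the standard deviation of the additive
    Gaussian noise on log power (multiplicative lognormal on power);
    ``end_spurt`` optionally lifts the final bin's mean log power.
    """

    bin_log_power: tuple[float, ...] = (2.0, 2.2, 2.1, 2.3, 1.9)
    sigma: float = 0.5
    end_spurt: float = 0.0

    def __post_init__(self) -> None:
        _check(np.all(np.isfinite(self.bin_log_power)), "bin means must be finite")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")


def generate_gamma_series(
    n_trials: int,
    spec: GammaTrendSpec | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "sim",
) -> GammaSeries:
    """Draw a strictly positive per-trial gamma-power series.

    Bin labels are assigned by trial-index proportion (trial i of n falls
    in bin floor(5*i/n)+1), the noise-free power in bin b is
    exp(bin_log_power[b]), and trial noise is lognormal.
    """
    _check(n_trials >= 1, "n_trials must be >= 1")
    spec = spec or GammaTrendSpec()
    rng = rng if rng is not None else np.random.default_rng()
    n_bins = len(spec.bin_log_power)
    bins = (np.arange(n_trials) * n_bins) // n_trials + 1
    mu = np.asarray(spec.bin_log_power, dtype=float).copy()
    mu[-1] += spec.end_spurt
    log_power = mu[bins - 1]
    if spec.sigma > 0:
        log_power = log_power + rng.normal(0.0, spec.sigma, size=n_trials)
    return GammaSeries(subject=subject, gamma=np.exp(log_power), bins=bins)


@dataclass
class SyntheticCohort:
    """Ground-truth-coupled cohort: behaviour, gamma, zeta, and true params."""

    variant: str
    sessions: list[SessionResult]
    gamma: list[GammaSeries]
    zeta: list[np.ndarray]
    true_params: list[ModelParams]


def _expected_trials(task: TaskConfig) -> int:
    mean_isi = float(np.mean(task.isi_values))
    return int(task.duration_s / (mean_isi + 0.4))


def generate_synthetic_cohort(
    n_subjects: int,
    variant: str,
    param_sampler: Callable[[np.random.Generator], ModelParams],
    trend_spec: GammaTrendSpec | None = None,
    task: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    zeta_config: ZetaConfig | None = None,
) -> SyntheticCohort:
    """Simulate a cohort whose emitted gamma/zeta is exactly what drove it.

    For the gamma variants, each subject's gamma series is generated
    first (sized to the expected trial count, with a generous buffer since
    the realised count is emergent), transformed to zeta, and that same
    zeta series both moderates the simulation and is returned truncated to
    the realised trial count — the ground-truth coupling that parameter-
    and model-recovery tests rely on.
    """
    _check(n_subjects >= 1, "n_subjects must be >= 1")
    task = task or TaskConfig()
    trend_spec = trend_spec or GammaTrendSpec()
    rng = rng if rng is not None else np.random.default_rng()
    n_exp = _expected_trials(task)
    n_buffer = 3 * n_exp

    sessions: list[SessionResult] = []
    gammas: list[GammaSeries] = []
    zetas: list[np.ndarray] = []
    trues: list[ModelParams] = []
    for i, sub_rng in enumerate(rng.spawn(n_subjects)):
        subject = f"s{i + 1:03d}"
        params = param_sampler(sub_rng)
        if params.variant != variant:
            raise ParameterError("sampled params variant does not match cohort variant")
        if variant == "cmf":
            zeta_by_trial = None
        else:
            # buffer series laid out against the expected count; labels beyond
            # the expected count stay in the final bin
            g_core = generate_gamma_series(n_exp, trend_spec, sub_rng, subject)
            extra = n_buffer - n_exp
            mu_last = trend_spec.bin_log_power[-1] + trend_spec.end_spurt
            g_extra = np.exp(mu_last + sub_rng.normal(0.0, trend_spec.sigma, size=extra)) \
                if trend_spec.sigma > 0 else np.full(extra, np.exp(mu_last))
            gamma = GammaSeries(
                subject=subject,
                gamma=np.concatenate([g_core.gamma, g_extra]),
                bins=np.concatenate([g_core.bins, np.full(extra, g_core.bins[-1])]),
            )
            if variant == "gamma1":
                bin_means = [gamma.gamma[: n_exp][g_core.bins == b].mean()
                             for b in sorted(set(g_core.bins.tolist()))]
                zs = zeta_binned(np.asarray(bin_means))
                zeta_by_trial = per_trial_zeta(gamma, zs)
            else:
                zs = zeta_trial(gamma, zeta_config or ZetaConfig())
                zeta_by_trial = zs.zeta
        session = simulate_session(variant, params, task, zeta_by_trial, sub_rng, subject)
        n_real = session.n_trials
        if variant != "cmf":
            gammas.append(GammaSeries(subject, gamma.gamma[:n_real], gamma.bins[:n_real]))
            zetas.append(np.asarray(zeta_by_trial)[:n_real].copy())
        sessions.append(session)
        trues.append(params)
    return SyntheticCohort(variant=variant, sessions=sessions, gamma=gammas,
                           zeta=zetas, true_params=trues)


def generate_synthetic_epochs(
    n_trials: int,
    rate: float = 512.0,
    span_ms: tuple[float, float] = (-1500.0, 1500.0),
    band: tuple[float, float] = (70.0, 80.0),
    bin_amplitudes: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0),
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> EpochMatrix:
    """White noise plus in-band sinusoidal bursts inside -300..800 ms.

    Each trial's burst frequency is drawn uniformly inside ``band`` and its
    amplitude follows the per-bin profile (bins by trial-index proportion).
    """
    _check(n_trials >= 1, "n_trials must be >= 1")
    if band[1] >= rate / 2.0:
        raise ParameterError(f"band {band} exceeds the Nyquist frequency {rate / 2} Hz")
    if any(a < 0 for a in bin_amplitudes):
        raise ParameterError("burst amplitudes must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = span_ms
    n_samples = int(np.floor((hi - lo) * rate / 1000.0))
    t = np.arange(n_samples) / rate + lo / 1000.0  # seconds relative to onset
    burst_mask = (t >= -0.300) & (t < 0.800)
    n_bins = len(bin_amplitudes)
    bins = (np.arange(n_trials) * n_bins) // n_trials + 1
    data = rng.normal(0.0, noise_sd, size=(n_trials, n_samples)) if noise_sd > 0 \
        else np.zeros((n_trials, n_samples))
    freqs = rng.uniform(band[0], band[1], size=n_trials)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    for i in range(n_trials):
        amp = bin_amplitudes[bins[i] - 1]
        if amp > 0:
            data[i, burst_mask] += amp * np.sin(2.0 * np.pi * freqs[i] * t[burst_mask] + phases[i])
    return EpochMatrix(data, rate=rate, span_ms=span_ms)
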