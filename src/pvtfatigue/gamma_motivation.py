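"""Transform gamma-band power into the motivation parameter zeta.

zeta indexes momentary effort relative to a baseline: 1 means baseline
effort, values above 1 compensatory (end-spurt) effort, values below 1
diminished effort.  Two transforms are provided, mirroring the two model
variants that consume them:

* binned (Model 1): per-2-minute-bin power, normalised by the first bin
  and the range, so the first bin is exactly 1 and all values lie in [0, 2];
* single-trial (Model 2): a decibel-style log-ratio of each trial's power
  against the mean power of the first ``k`` trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ParameterError, _check

__all__ = [
    "GammaSeries",
    "ZetaConfig",
    "ZetaSeries",
    "zeta_binned",
    "zeta_trial",
    "baseline_mean",
    "read_gamma_csv",
    "write_zeta_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class GammaSeries:
    """Per-trial gamma power for one subject (strictly positive, 1-based trials)."""

    subject: str
    gamma: np.ndarray
    bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        _check(self.gamma.size >= 1, "gamma series must contain at least one trial")
        if not np.all(self.gamma > 0.0):
            raise ParameterError("gamma power values must be strictly positive")
        if self.bins is not None:
            self.bins = np.asarray(self.bins, dtype=int)
            _check(self.bins.size == self.gamma.size, "bin labels must match series length")

    def __len__(self) -> int:
        return int(self.gamma.size)


@dataclass(frozen=True)
class ZetaConfig:
    """Settings for the single-trial transform.

    ``k`` baseline-trial count (default 10); ``b`` logarithm base, by
    convention a multiple of 10 with default 10, though any real base > 1
    is accepted (with a warning) since nothing in the transform requires
    the restriction.
    """

    mode: str = "trial"
    k: int = 10
    b: float = 10.0

    def __post_init__(self) -> None:
        _check(self.mode in ("binned", "trial"), f"unknown zeta mode {self.mode!r}")
        _check(self.k >= 1, f"baseline trial count k must be >= 1, got {self.k}")
        _check(self.b > 1.0, f"log base b must be > 1, got {self.b}")
        if not (self.b >= 10.0 and float(self.b) % 10.0 == 0.0):
            warnings.warn(
                f"log base b={self.b} is not a multiple of 10; accepted, but the "
                "conventional choice is 10, 20, 30, ...",
                stacklevel=2,
            )


@dataclass
class ZetaSeries:
    """Per-bin or per-trial motivation values (unitless, >= 0)."""

    subject: str
    zeta: np.ndarray
    mode: str = "trial"
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        _check(np.all(self.zeta >= 0.0), "zeta cannot go below zero")

    def __len__(self) -> int:
        return int(self.zeta.size)


def zeta_binned(binned_gamma: np.ndarray) -> ZetaSeries:
    """Bin-level transform: zeta_t = 1 + (gamma_t - gamma_1) / range(gamma).

    The first bin is exactly 1 and every value lies in [0, 2].  A constant
    series has zero range; by convention it maps to all-ones (effort at
    baseline throughout) with a warning rather than an error.
    """
    g = np.asarray(binned_gamma, dtype=float)
    _check(g.size >= 2, "binned transform needs at least two bins")
    if not np.all(g > 0.0):
        raise ParameterError("gamma power values must be strictly positive")
    rng_ = g.max() - g.min()
    if rng_ == 0.0:
        warnings.warn("zero range in binned gamma; returning constant zeta = 1", stacklevel=2)
        return ZetaSeries(subject="", zeta=np.ones_like(g), mode="binned")
    z = 1.0 + (g - g[0]) / rng_
    return ZetaSeries(subject="", zeta=z, mode="binned")


def baseline_mean(series: GammaSeries, k: int) -> float:
    """Arithmetic mean of the first k trials' gamma power."""
    _check(k >= 1, f"k must be >= 1, got {k}")
    if k > len(series):
        raise ParameterError(f"k={k} exceeds series length {len(series)}")
    return float(np.mean(series.gamma[:k]))


def zeta_trial(series: GammaSeries, config: ZetaConfig | None = None) -> ZetaSeries:
    """Single-trial transform: zeta_t = 1 + log_b(gamma_t / mean(gamma_1..k)).

    The baseline mean is computed once from trials 1..k and applied to all
    trials, including the baseline trials themselves (whose zeta therefore
    hovers near 1).  Values can exceed 1 (extra effort); values driven
    below 0 by very small trial power are clamped at 0 with a logged count,
    since effort cannot go below "absolute" fatigue.
    """
    config = config or ZetaConfig()
    if len(series) <= config.k:
        raise ParameterError(
            f"series length {len(series)} must exceed baseline count k={config.k}"
        )
    mu = baseline_mean(series, config.k)
    z = 1.0 + np.log(series.gamma / mu) / np.log(config.b)
    n_clamped = int(np.sum(z < 0.0))
    if n_clamped:
        logger.info(
            "clamped %d of %d zeta values at 0 for subject %s",
            n_clamped, len(series), series.subject,
        )
        z = np.maximum(z, 0.0)
    return ZetaSeries(subject=series.subject, zeta=z, mode="trial", n_clamped=n_clamped)


def read_gamma_csv(path) -> list[GammaSeries]:
    """Read a gamma CSV (columns subject, trial, gamma_power[, bin])."""
    df = pd.read_csv(path)
    required = {"subject", "trial", "gamma_power"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"gamma CSV missing columns: {sorted(missing)}")
    out = []
    for subject, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        bins = grp["bin"].to_numpy() if "bin" in grp.columns else None
        out.append(GammaSeries(subject=str(subject), gamma=grp["gamma_power"].to_numpy(), bins=bins))
    return out


def per_trial_zeta(series: GammaSeries, zeta: ZetaSeries) -> np.ndarray:
    """Expand a ZetaSeries to one value per trial.

    Trial-mode series already align one-to-one; binned series are mapped
    through the trial bin labels (every trial inherits its bin's zeta).
    """
    if len(zeta) == len(series):
        return zeta.zeta
    if zeta.mode == "binned" and series.bins is not None:
        return zeta.zeta[series.bins - 1]
    raise ParameterError(
        "zeta series length does not match trials and no bin labels are available"
    )


def write_zeta_csv(path, series: GammaSeries, zeta: ZetaSeries) -> None:
    """Write gamma + zeta side by side, mirroring the input layout."""
    df = pd.DataFrame(
        {
            "subject": series.subject,
            "trial": np.arange(1, len(series) + 1),
            "gamma_power": series.gamma,
            "zeta": per_trial_zeta(series, zeta),
        }
    )
    if series.bins is not None:
        df["bin"] = series.bins
    df.to_csv(path, index=False)
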