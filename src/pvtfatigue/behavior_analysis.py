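"""Behavioural analyses for PVT trial tables.

Response typing (false start / alert / lapse / sleep attack), 2-minute
time binning, the inverse-RT speed transform, per-subject RT quintile
tables with a chi-square test of independence, and the lagged
gamma-power-to-RT cross-correlation with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gamma_motivation import GammaSeries
from .model_core import ParameterError, _check

__all__ = [
    "ResponseRules",
    "classify_response",
    "assign_time_bins",
    "inverse_rt",
    "quintile_table",
    "chi_square_independence",
    "lagged_crosscorr_bootstrap",
]


@dataclass(frozen=True)
class ResponseRules:
    """Response-class boundaries in milliseconds.

    The pre-stimulus rule takes precedence; the remaining bands partition
    the positive RT axis: false start below ``alert_lo``, alert in
    [alert_lo, lapse_lo], lapse above ``lapse_lo``, sleep attack at or
    beyond ``sleep_ms``.
    """

    alert_lo: float = 150.0
    lapse_lo: float = 500.0
    sleep_ms: float = 30_000.0


DEFAULT_RULES = ResponseRules()


def classify_response(
    rt_ms: float, pressed_pre_stimulus: bool = False, rules: ResponseRules = DEFAULT_RULES
) -> str:
    """Deterministically label one response."""
    if pressed_pre_stimulus:
        return "false_start"
    if not np.isfinite(rt_ms) or rt_ms <= 0:
        raise ParameterError(f"rt_ms must be positive without the pre-stimulus flag, got {rt_ms}")
    if rt_ms < rules.alert_lo:
        return "false_start"
    if rt_ms >= rules.sleep_ms:
        return "sleep_attack"
    if rt_ms <= rules.lapse_lo:
        return "alert"
    return "lapse"


def assign_time_bins(onset_s: float | np.ndarray, duration_s: float = 600.0, n_bins: int = 5):
    """Map stimulus-onset times to 2-minute bins 1..5.

    Bins are right-open 120 s intervals except the final bin, which is
    closed at the session end so that [0, 600] is partitioned exactly.
    """
    onset = np.asarray(onset_s, dtype=float)
    if np.any(onset < 0) or np.any(onset > duration_s):
        raise ParameterError("onset time outside the session")
    width = duration_s / n_bins
    bins = np.minimum(onset // width, n_bins - 1).astype(int) + 1
    return bins if bins.ndim else int(bins)


def inverse_rt(rt_ms: float | np.ndarray):
    """Speed score 1000 / RT (the 1/RT x 1000 transform reducing mean-RT skew)."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ParameterError("rt_ms must be positive")
    out = 1000.0 / rt
    return out if out.ndim else float(out)


def _quintile_labels(rts: np.ndarray, n_q: int = 5) -> np.ndarray:
    """Rank-order RTs (stable; ties by trial order) into near-equal quintiles.

    Quintile sizes differ by at most one; fastest responses are Q1.
    """
    order = np.argsort(rts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(rts.size)
    return (rank * n_q) // rts.size + 1


def quintile_table(
    trials: pd.DataFrame, duration_s: float = 600.0, n_bins: int = 5
) -> pd.DataFrame:
    """Aggregate per-subject RT-quintile membership counts by time bin.

    ``trials`` needs columns subject, onset_s, rt_ms; only classifiable
    (finite, positive) RTs enter.  Each subject's RTs are rank-ordered and
    cut into quintiles (fastest = Q1); counts per (bin, quintile) cell are
    summed across subjects.  Subjects with fewer than five classifiable
    RTs are excluded with a warning.
    """
    table = np.zeros((n_bins, 5), dtype=int)
    for subject, grp in trials.groupby("subject", sort=False):
        ok = np.isfinite(grp["rt_ms"].to_numpy()) & (grp["rt_ms"].to_numpy() > 0)
        grp = grp.loc[ok]
        if len(grp) < 5:
            warnings.warn(f"subject {subject!r} has <5 classifiable RTs; excluded", stacklevel=2)
            continue
        q = _quintile_labels(grp["rt_ms"].to_numpy())
        b = assign_time_bins(grp["onset_s"].to_numpy(), duration_s, n_bins)
        np.add.at(table, (b - 1, q - 1), 1)
    return pd.DataFrame(
        table,
        index=[f"bin{i + 1}" for i in range(n_bins)],
        columns=[f"Q{j + 1}" for j in range(5)],
    )


def chi_square_independence(table) -> tuple[float, int]:
    """Pearson chi-square of independence (no continuity correction).

    Returns (statistic, df) with df = (r-1)(c-1); a 5x5 quintile-by-bin
    table therefore has df = 16.
    """
    arr = np.asarray(table, dtype=float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ParameterError("chi-square is undefined with a zero row or column margin")
    stat, _, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df)


def lagged_crosscorr_bootstrap(
    gamma: GammaSeries | np.ndarray,
    rts: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Pearson r between lagged gamma power (k-1) and current-trial RT (k).

    Resamples the (gamma_{k-1}, RT_k) pairs i.i.d. ``n_boot`` times and
    returns the percentile confidence interval alongside the point
    estimate.
    """
    g = gamma.gamma if isinstance(gamma, GammaSeries) else np.asarray(gamma, dtype=float)
    r_t = np.asarray(rts, dtype=float)
    _check(g.size == r_t.size, "gamma and RT series must be aligned")
    _check(g.size >= 3, "need at least three trials")
    _check(n_boot >= 100, "n_boot must be >= 100")
    x, y = g[:-1], r_t[1:]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined: a series has zero variance")
    rng = rng if rng is not None else np.random.default_rng()
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    bx_c = bx - bx.mean(axis=1, keepdims=True)
    by_c = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx_c**2).sum(axis=1) * (by_c**2).sum(axis=1))
    valid = denom > 0
    boot = (bx_c * by_c).sum(axis=1)[valid] / denom[valid]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return r, (float(lo), float(hi))
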