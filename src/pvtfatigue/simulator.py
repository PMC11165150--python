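"""Forward simulation of Psychomotor Vigilance Test (PVT) sessions.

The task process follows the classic wait/attend/respond production cycle:

* during the interstimulus interval (ISI, discrete uniform 2..10 s) the
  model resolves conflicts between ``wait`` (state-appropriate) and
  ``respond`` (mismatching, penalised); a rare ``respond`` firing yields a
  false start;
* once the millisecond counter appears, ``attend`` competes with the now
  mismatching ``wait``; after attending, ``respond`` fires and the key
  goes down ``t_motor`` seconds later;
* any conflict-resolution cycle in which no production's noisy utility
  clears the threshold is a microlapse: it consumes the cycle time plus a
  50 ms penalty and multiplies subsequent utilities by lambda, so
  microlapses beget microlapses and stretch the RT tail rightward;
* no keypress within 30 s of stimulus onset is a sleep attack.

Time-on-task ``t`` (minutes) advances continuously at cycle resolution.
The microlapse moderator count feeding the utility equations resets at
each engagement boundary (trial start and stimulus onset); the session
keeps a cumulative count for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    FatigueState,
    ModelParams,
    ParameterError,
    SelectionContext,
    MICROLAPSE,
    moderated_threshold,
    moderated_utility,
    resolve_conflict,
    _check,
)

__all__ = [
    "TaskConfig",
    "TrialOutcome",
    "SessionResult",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "sessions_to_frame",
    "write_sessions",
    "read_sessions",
]

RT_SENTINEL = float("nan")


@dataclass(frozen=True)
class TaskConfig:
    """PVT task structure: 10-min session, integer 2-10 s ISIs, 30 s timeout."""

    duration_s: float = 600.0
    isi_values: tuple[int, ...] = tuple(range(2, 11))
    timeout_s: float = 30.0

    def __post_init__(self) -> None:
        _check(self.duration_s > 0, "session duration must be positive")
        _check(self.timeout_s > 0, "timeout must be positive")
        _check(
            all(2 <= v <= 10 and float(v).is_integer() for v in self.isi_values),
            "ISI support must be integer seconds within [2, 10]",
        )


@dataclass
class TrialOutcome:
    """One realised PVT trial."""

    trial: int
    onset_s: float
    isi_s: float
    rt_ms: float  # NaN for false starts and sleep attacks
    response: str  # false_start | alert | lapse | sleep_attack
    n_microlapses: int
    zeta: float


@dataclass
class SessionResult:
    """All trials of one simulated (or observed) session."""

    subject: str
    variant: str
    params: ModelParams | None
    trials: list[TrialOutcome]
    state: FatigueState

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(t) for t in self.trials])
        df.insert(0, "subject", self.subject)
        return df

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _classify(rt_ms: float, pre_stimulus: bool, timeout_s: float) -> str:
    # mirrors behavior_analysis.classify_response; kept local to avoid a cycle
    if pre_stimulus or rt_ms < 150.0:
        return "false_start"
    if rt_ms >= timeout_s * 1000.0:
        return "sleep_attack"
    if rt_ms <= 500.0:
        return "alert"
    return "lapse"


def simulate_trial(
    params: ModelParams,
    state: FatigueState,
    zeta: float,
    task: TaskConfig,
    isi_s: float,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate one trial starting at session time ``state.t`` minutes.

    Advances ``state`` in place (time-on-task and cumulative microlapses)
    and returns the trial outcome.  ``zeta`` must be 1 for the CMF variant.
    """
    if params.variant == "cmf":
        _check(zeta == 1.0, "CMF takes no motivation input; pass zeta = 1")
    delta = params.mismatch_penalty
    t_start_min = state.t
    onset_abs_s = t_start_min * 60.0 + isi_s
    elapsed = 0.0  # seconds since trial start
    n_local = 0  # moderator count since last engagement boundary
    n_total = 0  # all microlapses this trial (reported)

    # --- pre-stimulus phase: {wait, respond(-delta)} -----------------------
    # the cycle clock runs freely through the ISI, so the stimulus usually
    # appears mid-cycle (or mid-penalty) and the response phase inherits
    # the clock overshoot.  While waiting there is no response goal to
    # degrade, so waiting microlapses occur at the base rate without
    # cascading (the moderator count stays 0 until stimulus onset); they
    # still consume the 50 ms penalty and are counted.  Cycle time is
    # recomputed from counts to avoid float drift.
    press_s: float | None = None  # seconds relative to stimulus onset
    n_cycles = 0
    while elapsed < isi_s:
        t_min = t_start_min + elapsed / 60.0
        u = moderated_utility(params, 0, t_min, zeta)
        ut = moderated_threshold(params, t_min)
        ctx = SelectionContext(utilities=(u, u - delta), threshold=ut, s=params.s)
        fired = resolve_conflict(ctx, rng)
        n_cycles += 1
        if fired == MICROLAPSE:
            n_total += 1
        elapsed = n_cycles * params.phi + n_total * params.t_microlapse
        if fired == 1:  # respond before the stimulus
            press_s = elapsed + params.t_motor - isi_s
            break

    if press_s is not None and press_s < 0.150:
        # keypress before (or in the anticipation range of) the counter
        state.advance((elapsed + params.t_motor) / 60.0)
        state.record_microlapses(n_total)
        return TrialOutcome(
            trial=-1,
            onset_s=onset_abs_s,
            isi_s=isi_s,
            rt_ms=RT_SENTINEL,
            response="false_start",
            n_microlapses=n_total,
            zeta=zeta,
        )

    # --- response phase: attend then respond -------------------------------
    if press_s is None:
        since_onset = max(elapsed - isi_s, 0.0)  # cycle overshoot at onset
        n_local = 0  # re-engagement at stimulus onset
        phase_attending = True
        while True:
            if since_onset >= task.timeout_s:
                state.advance((isi_s + task.timeout_s) / 60.0)
                state.record_microlapses(n_total)
                return TrialOutcome(
                    trial=-1,
                    onset_s=onset_abs_s,
                    isi_s=isi_s,
                    rt_ms=RT_SENTINEL,
                    response="sleep_attack",
                    n_microlapses=n_total,
                    zeta=zeta,
                )
            t_min = t_start_min + (isi_s + since_onset) / 60.0
            u = moderated_utility(params, n_local, t_min, zeta)
            ut = moderated_threshold(params, t_min)
            if phase_attending:
                ctx = SelectionContext(utilities=(u, u - delta), threshold=ut, s=params.s)
            else:
                ctx = SelectionContext(utilities=(u,), threshold=ut, s=params.s)
            fired = resolve_conflict(ctx, rng)
            since_onset += params.phi
            if fired == MICROLAPSE:
                since_onset += params.t_microlapse
                n_local += 1
                n_total += 1
            elif phase_attending and fired == 0:
                phase_attending = False
            elif not phase_attending and fired == 0:
                press_s = since_onset + params.t_motor
                break
            # attending phase, fired == 1: mismatching wait wasted the cycle

    rt_ms = press_s * 1000.0
    state.advance((isi_s + press_s) / 60.0)
    state.record_microlapses(n_total)
    return TrialOutcome(
        trial=-1,
        onset_s=onset_abs_s,
        isi_s=isi_s,
        rt_ms=rt_ms,
        response=_classify(rt_ms, False, task.timeout_s),
        n_microlapses=n_total,
        zeta=zeta,
    )


def simulate_session(
    variant: str,
    params: ModelParams,
    task: TaskConfig | None = None,
    zeta_series: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "sim",
) -> SessionResult:
    """Chain trials with fresh ISI draws until the session duration elapses.

    ``zeta_series`` supplies one motivation value per trial for the gamma
    variants (required there, forbidden meaning for CMF); if the realised
    trial count outruns the series it is extended by its last value with a
    warning.
    """
    import warnings

    task = task or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    _check(params.variant == variant, "params.variant must match the requested variant")
    if variant in ("gamma1", "gamma2"):
        if zeta_series is None:
            raise ParameterError(f"{variant} requires a zeta series")
        zeta_series = np.asarray(zeta_series, dtype=float)
    else:
        _check(zeta_series is None, "CMF takes no zeta series")

    state = FatigueState()
    trials: list[TrialOutcome] = []
    warned_short = False
    while True:
        isi = float(rng.choice(task.isi_values))
        if state.t * 60.0 + isi >= task.duration_s:
            break
        idx = len(trials)
        if variant == "cmf":
            zeta = 1.0
        else:
            if idx >= len(zeta_series):
                if not warned_short:
                    warnings.warn(
                        "zeta series shorter than realised trial count; "
                        "extending by last value",
                        stacklevel=2,
                    )
                    warned_short = True
                zeta = float(zeta_series[-1])
            else:
                zeta = float(zeta_series[idx])
        outcome = simulate_trial(params, state, zeta, task, isi, rng)
        outcome.trial = idx + 1
        trials.append(outcome)
    return SessionResult(subject=subject, variant=variant, params=params,
                         trials=trials, state=state)


def simulate_cohort(
    n_subjects: int,
    param_sampler: Callable[[np.random.Generator], ModelParams],
    variant: str,
    task: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    zeta_sampler: Callable[[np.random.Generator], Sequence[float]] | None = None,
) -> list[SessionResult]:
    """Independent per-subject parameter draws and sessions.

    Each subject runs on a child RNG stream spawned from the root seed, so
    cohorts are reproducible and order-independent.
    """
    _check(n_subjects >= 1, "n_subjects must be >= 1")
    task = task or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    streams = rng.spawn(n_subjects)
    results = []
    for i, sub_rng in enumerate(streams):
        params = param_sampler(sub_rng)
        zeta = zeta_sampler(sub_rng) if zeta_sampler is not None else None
        results.append(
            simulate_session(variant, params, task, zeta, sub_rng, subject=f"s{i + 1:03d}")
        )
    return results


def sessions_to_frame(sessions: Sequence[SessionResult]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def write_sessions(path_csv, sessions: Sequence[SessionResult], seed: int | None = None) -> None:
    """Write trial table CSV plus a JSON sidecar with parameters and seed."""
    sessions_to_frame(sessions).to_csv(path_csv, index=False)
    sidecar = {
        "seed": seed,
        "subjects": {
            s.subject: {
                "variant": s.variant,
                "params": None if s.params is None else asdict(s.params),
            }
            for s in sessions
        },
    }
    with open(str(path_csv) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_sessions(path_csv) -> pd.DataFrame:
    """Read a trial table written by :func:`write_sessions` (or observed data)."""
    df = pd.read_csv(path_csv)
    required = {"subject", "trial", "onset_s", "isi_s", "rt_ms", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"session CSV missing columns: {sorted(missing)}")
    return df
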