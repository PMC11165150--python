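# Methods

## The task and the process model

The package models the 10-minute Psychomotor Vigilance Test (PVT): a
millisecond counter appears after a discrete-uniform 2–10 s interstimulus
interval (ISI) and the participant presses a key as fast as possible.
Responses are typed as false starts (pre-stimulus press or RT < 150 ms),
alert responses (150–500 ms), lapses (> 500 ms), and sleep attacks (no
press within 30 s).

Behaviour is generated by a production cycle in the ACT-R style.  Every
ϕ seconds a conflict-resolution cycle selects among the productions that
match the current task state:

* waiting (pre-stimulus): `wait` matches; `respond` mismatches;
* stimulus on screen: `attend` matches; `wait` mismatches;
* after attending: `respond` matches.

All productions share a single moderated utility `U`; a mismatching
candidate competes at `U − δ`, with the mismatch penalty δ = 10 by
default.  Each cycle, every candidate receives independent logistic noise
with scale `s` (variance π²s²/3, default s = 0.45).  If no candidate's
noisy utility clears the utility threshold `UT`, the cycle is a
**microlapse**: it consumes ϕ plus a 50 ms penalty and multiplies
subsequent utilities by λ, so microlapses breed microlapses and stretch
the RT distribution rightward.  Otherwise one production fires, drawn from
the Luce soft-max `exp(U_i / 2s) / Σ exp(U_j / 2s)`.

Sampling the two printed laws directly — the microlapse gate with
probability `Π_j F((UT − U_j)/s)` and the soft-max selection — is a
deliberate choice over "fire the noisy maximum".  The noisy-max process
does *not* reproduce the soft-max choice probabilities (the difference of
two logistic variates is not logistic with doubled scale; the discrepancy
is several percent at unit utility gaps), so a simulator built on
noisy-max would contradict the closed-form selection law the model
states.  With the gate-plus-soft-max mechanism both closed forms hold
exactly, and false starts still emerge from the vanishing soft-max mass of
the mismatching `respond` (about 1.5·10⁻⁵ per cycle at the defaults,
yielding roughly one false start per thousand trials, the scale observed
empirically).

Timing: the noise-free response path is attend + respond = 2 cycles, so
the RT floor is 2ϕ + t_motor ≈ 215 ms with ϕ ≈ 0.057 s and a 100 ms motor
time.  The cycle clock runs freely through the ISI, so the stimulus
usually appears mid-cycle and the response phase inherits the clock
overshoot — a small offset (the residual of the straddling cycle or
penalty, under ϕ + 50 ms) that keeps simulated RTs continuous rather
than confined to the cycle lattice (important downstream: rank-based
analyses degenerate on heavily tied RTs).  Stimulus onset re-engages the
system and resets the microlapse moderator.  Time-on-task
`t` advances continuously at cycle resolution and enters the equations in
minutes.

## Moderated utilities

CMF (computational model of fatigue):

    U(t)  = υ · λ^N_ml · (1 + t)^ρ
    UT(t) = τ · (1 + t)^κ

Gamma models replace the time-on-task penalty with a motivation value ζ
derived from EEG high-gamma (70–80 Hz) power, and hold the threshold at τ:

    U = υ · λ^N_ml · ζ

`ζ = 1` is baseline effort; values above 1 buy back performance
(end-spurt), values below 1 model disengagement.  Model 1 computes ζ per
2-minute bin, `ζ_t = 1 + (γ_t − γ_1)/range(γ)` (first bin exactly 1,
range [0, 2]); Model 2 computes it per trial as a decibel-style ratio,
`ζ_t = 1 + log_b(γ_t / mean(γ_1..k))` with baseline count k = 10 and
log base b = 10, clamped at 0 (effort cannot fall below "absolute"
fatigue).

**Microlapse bookkeeping.**  The `N_ml` entering the utility equations
counts microlapses since stimulus onset: the cascade describes the
degradation of goal-directed response processing.  While waiting there is
no response goal to degrade, so pre-stimulus microlapses occur at the
base rate without cascading — they consume their 50 ms penalties and are
counted in the session totals, and they make the pre-stimulus process
i.i.d. per cycle, which is what lets the fitting kernel reproduce the
onset-offset distribution in closed form.  A session-cumulative moderator
is untenable: cycling accrues one to two microlapses per trial, and λ^N
with any fitted λ (0.88–0.98) would drive the utility to zero within
minutes, turning every late trial into a 30 s timeout — incompatible
with sessions that are ~94% alert responses.  The within-trial cascade
(the mechanism that produces lapses) is retained where it matters, while
time-on-task and ζ carry the slow fatigue signal.

**Mismatch penalty δ = 10.**  Chosen so the soft-max mass of a
mismatching production, e^{−δ/2s} ≈ 1.5·10⁻⁵ per cycle at s = 0.45,
produces false starts at the per-mille rate characteristic of rested
10-minute PVT sessions.  δ is a constant of the task architecture, not a
fitted parameter.

## Parameters

| name | meaning | default / bounds | units |
| --- | --- | --- | --- |
| υ | initial production utility | free, (0, ∞), prior box (0, 20] | – |
| τ | initial utility threshold | fixed 2.0 | – |
| λ | microlapse penalty | free, (0, 1) | – |
| ϕ | conflict-resolution cycle time | free, (0.01, 0.1) | s |
| ρ | utility time-on-task exponent | free, (−1, 0); CMF only | – |
| κ | threshold time-on-task exponent | free, (−1, 0]; CMF only | – |
| s | utility-noise scale | 0.45, config constant | – |
| t_microlapse | microlapse time penalty | 0.050 | s |
| t_motor | motor execution time | 0.100 | s |
| δ | mismatch penalty | 10.0 | – |

κ may equal 0 while ρ may not, honouring the published bound asymmetry.
The prior box truncates υ at 20 (an order of magnitude above the fixed
threshold) so the uniform prior is proper.  s is not fitted: it trades off
against υ/τ scale and is conventionally held at a mid-range value.

## Simulated likelihood and fitting

Because the microlapse moderator resets at stimulus onset, a trial's RT
distribution depends only on its (t, ζ) condition and the likelihood
factorises over trials.  At a proposed parameter vector the response
phase is simulated under each observed condition.  CMF and Model 1 group
trials by 2-minute bin (ζ is constant within a bin); Model 2's conditions
depend on ζ alone, so its trials pool into 12 ζ-quantile bins — enough
draws per condition to resolve the few-percent microlapse-bump masses —
and each bin's simulated draws cycle through its member trials' exact ζ
values, so the bin density is the mixture over member conditions
(simulating at the bin-mean ζ understates bump masses, since the
microlapse probability is convex in ζ).  The (ζ, onset) canonical sort
makes the likelihood exactly invariant to row order.  `n_sim` total draws
(default 2,000) are split evenly across conditions and scored as a
defective mixture: point masses for sleep attacks (simulated timeout
frequency) and false starts (closed-form per-cycle probability over a
mean-length ISI), plus an RT density.  The default density is a
fixed-bandwidth (15 ms) Gaussian KDE over responses faster than 1 s,
with slower responses scored by the simulated tail mass spread uniformly
out to the timeout.  Each piece of that design carries a failure mode it
avoids: adaptive bandwidths reward proposals that concentrate all mass at
the RT floor (the bandwidth shrinks and the density spikes, biasing υ
upward); pure fixed-bin histograms starve sparsely simulated conditions;
and a narrow kernel alone cannot credit diffuse multi-second lapses,
which is where the cascade (λ) signal lives.  A 10-ms histogram density
remains available.  Every mass is floored at ε = 10⁻⁶ so no observation
scores −∞.  The simulated trials start from the onset clock offset drawn
from its closed-form distribution: the residual life of the straddling
pre-stimulus event, length-biased between plain ϕ cycles and ϕ + 50 ms
microlapse events (the forward and fitting simulators agree to
Monte-Carlo precision on this and on the full RT mixture; the agreement
is asserted in tests).

Sampling is differential-evolution MCMC: chains (4 per free parameter)
propose `θ_k + γ_DE (θ_r1 − θ_r2) + U(−10⁻⁴, 10⁻⁴)` with
γ_DE = 2.38/√(2d), reflecting off the bounds, under uniform priors; every
10th iteration uses γ = 1, the standard full-length move that lets chains
jump between separated modes.  Chains start from the best points of an
8-chains-sized Latin-hypercube scan, half of whose points pin ϕ at the
value implied by the fastest observed response (the RT floor 2ϕ + t_motor
is where ϕ is identified).  During burn-in, chains stranded far below the
population (beyond Q1 − 2·IQR of held log-likelihoods) are reset to the
best chain's state.  Each proposal's simulation seed derives
deterministically from (root seed, chain, iteration), and the held
likelihood of the current state is re-evaluated on a fresh seed every
iteration — without this refresh, chains stick to lucky noise
realisations (acceptance ~3% instead of ~25%).  The point estimate is the
posterior mode under the uniform prior, computed by a Nelder–Mead ascent
of a seed-averaged (common-random-numbers) likelihood started from both
the converged-chain posterior mean and the best sampled vector;
non-converged chains (mean held likelihood more than 6 units below the
best chain's) are excluded from that mean.  The best-scoring sampled
vector is retained as `map_estimate` for inspection.  −2LL is
re-evaluated at the estimate with a dedicated seed and a fixed 256 draws
per condition, so AIC = −2LL + 2p (p = 5 for CMF, 3 for gamma models) is
comparable across variants whose conditions differ in granularity.

The response-phase simulator is JIT-compiled with numba when available
(a numpy fallback produces the same distribution; both are exercised in
tests).

## Spectral features

Per-trial high-gamma power follows the stated recipe: cut −300..+800 ms
from ±1,500 ms epochs (floor-indexed, half-open; 563 samples at 512 Hz),
Welch PSD with periodic 367 ms Hamming windows at 25% overlap, report on
2,560 linearly spaced frequencies over 0–256 Hz (each segment zero-padded
until the raw FFT grid is at least as dense, then linearly interpolated),
sum power over the inclusive [70, 80] Hz band, and natural-log transform.
The log base affects none of the downstream rank/ratio properties.

## Synthetic data

The generators emulate the study conditions rather than any particular
dataset: 34-subject cohorts, 10-minute sessions with integer 2–10 s ISIs
(≈ 60–110 trials emerging per session), per-trial gamma power that is
lognormal around a non-monotonic bin-level profile (default log-powers
(2.0, 2.2, 2.1, 2.3, 1.9): local peaks in bins 2 and 4, trough in bin 5,
matching the observed binned shape), trial-level log-noise σ = 0.5 (about
a ×3 spread between typical low and high trials, realistic for
single-trial band power and what makes λ identifiable, since low-ζ trials
probe the cascade regime), and an optional end-spurt uplift on the final
bin.  Synthetic EEG epochs are white noise plus 70–80 Hz sinusoidal
bursts confined to the analysis window — no 1/f background, artifacts, or
volume conduction, so passing tests certify the pipeline arithmetic, not
robustness to real EEG noise.  For gamma cohorts the ζ series that
moderated the simulation is emitted alongside the behaviour, giving the
ground-truth coupling that parameter- and model-recovery tests need.

## Numerical choices and degenerate inputs

* s = 0 degenerates cleanly: noise-free selection is argmax with
  lowest-index tie-break (flagged with a warning), the microlapse gate
  becomes an indicator product.
* Constant binned gamma (zero range) maps to ζ ≡ 1 with a warning rather
  than an error.
* ζ series shorter than the realised trial count is extended by its last
  value with a warning.
* Quintile cuts use stable ranking (ties by trial order) and near-equal
  quintile sizes (difference ≤ 1); time bins are right-open except the
  final bin, closed at the session end.
* Chi-square is the plain Pearson statistic without continuity
  correction; the cross-correlation bootstrap resamples (γ_{k−1}, RT_k)
  pairs i.i.d.
* Subjects with fewer than five classifiable RTs are excluded from the
  quintile table with a warning.

## Problem sizes

Default analysis sizes are chosen to keep full runs on one CPU
comfortable: parameter recovery uses 10 synthetic subjects at reduced
DE-MCMC settings (12 chains, 500 iterations, 2,000 simulated trials per
proposal); model-selection recovery uses 10 replicate two-subject cohorts
at further reduced settings; Monte-Carlo checks of the selection laws use
2·10⁵ draws.

## Known limitations

* The production set and timing constants reconstruct the published
  process description; no claim is made that RTs match the original
  implementation cycle for cycle.  Model claims are therefore tested as
  distributional properties, not pointwise RT equality.
* At the 30-minute-task moderator values (λ = 0.98, ρ = −0.05,
  κ = −0.01) a 10-minute session moves utility by only ~11%, and the
  model predicts per-trial lapse-rate changes of order 10⁻⁴–10⁻³ —
  far below what a per-session early/late comparison can detect.  Strong
  10-minute decrements require the larger penalties (ρ ≈ −0.2,
  κ ≈ −0.15, λ ≈ 0.88) that fits to 10-minute data produce.
* λ is weakly identified when υ·ζ stays far above the threshold; its
  recovery relies on low-motivation trials probing the cascade regime.
  For a single 10-minute session (~100 trials) the λ likelihood is often
  flat to within one or two log-likelihood units over [0.88, 1.0], with
  its maximum at the boundary for a sizeable fraction of simulated
  subjects — so per-subject λ point estimates carry irreducible ±0.05 to
  ±0.08 scatter regardless of estimator, while υ recovers to a few
  percent.
* The false-start mass in the likelihood uses a mean-length ISI and
  ignores pre-stimulus microlapse escalation (false starts are rare
  enough that the bias is negligible).
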