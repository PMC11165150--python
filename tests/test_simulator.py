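"""Tests of the trial/session process model."""

import math

import numpy as np
import pytest
from scipy.stats import logistic

from pvtfatigue import ModelParams, TaskConfig, simulate_session, simulate_trial
from pvtfatigue.model_core import FatigueState, ParameterError
from pvtfatigue.simulator import simulate_cohort


def _near_zero_noise_params(**kw):
    base = dict(variant="cmf", upsilon=3.0, lambda_ml=1.0, phi=0.05,
                rho=0.0, kappa=0.0, s=0.0)
    base.update(kw)
    return ModelParams(**base)


class TestSimulateTrial:
    def test_noise_free_rt_is_two_cycles_plus_motor(self, rng):
        params = _near_zero_noise_params()
        state = FatigueState()
        out = simulate_trial(params, state, 1.0, TaskConfig(), 5.0, rng)
        assert out.response == "alert"
        assert out.rt_ms == pytest.approx(2 * 0.05 * 1000 + 100.0, abs=1e-9)
        assert out.n_microlapses == 0

    def test_subthreshold_starvation_times_out(self, rng):
        params = _near_zero_noise_params(upsilon=1.0)  # upsilon < tau forever
        state = FatigueState()
        out = simulate_trial(params, state, 1.0, TaskConfig(), 2.0, rng)
        assert out.response == "sleep_attack"
        # every cycle from stimulus onset is a microlapse: phi + 50 ms each
        expected_post = math.floor(30.0 / (0.05 + 0.05))
        assert abs(out.n_microlapses - (expected_post + math.floor(2.0 / 0.1))) <= 2

    def test_false_start_frequency_matches_closed_form(self):
        # per-cycle false-start probability under the gate+softmax mechanism:
        # (1 - p_ml) * softmax(respond); measured over many single-cycle ISIs
        params = ModelParams(variant="cmf", upsilon=2.2, lambda_ml=1.0, phi=0.05,
                             rho=0.0, kappa=0.0, s=0.25, mismatch_penalty=0.6)
        u, delta, s, ut = 2.2, 0.6, 0.25, 2.0
        p_ml = float(logistic.cdf((ut - u) / s) * logistic.cdf((ut - u + delta) / s))
        p_resp = 1.0 / (1.0 + math.exp(delta / (2 * s)))
        q = (1.0 - p_ml) * p_resp
        n = 20_000
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(n):
            state = FatigueState()
            # ISI of one cycle: exactly one pre-stimulus conflict resolution
            out = simulate_trial(params, state, 1.0, TaskConfig(), 0.05, rng)
            hits += out.response == "false_start"
        se = math.sqrt(q * (1 - q) / n)
        assert abs(hits / n - q) < 4 * se

    def test_cmf_requires_unit_zeta(self, rng, cmf_params):
        with pytest.raises(ParameterError):
            simulate_trial(cmf_params, FatigueState(), 1.2, TaskConfig(), 5.0, rng)


class TestSimulateSession:
    def test_trial_count_within_renewal_bounds(self, rng, cmf_params):
        counts = [simulate_session("cmf", cmf_params, rng=rng).n_trials for _ in range(10)]
        assert all(600 / (10 + 30) <= n <= 600 / 2 for n in counts)
        # renewal expectation: mean count near duration / (mean ISI + mean RT)
        expected = 600 / (6 + 0.3)
        assert abs(np.mean(counts) - expected) < 0.12 * expected

    def test_seed_determinism(self, cmf_params):
        a = simulate_session("cmf", cmf_params, rng=np.random.default_rng(42))
        b = simulate_session("cmf", cmf_params, rng=np.random.default_rng(42))
        assert a.to_frame().equals(b.to_frame())

    def test_onsets_strictly_increasing_and_time_conserved(self, rng, cmf_params):
        res = simulate_session("cmf", cmf_params, rng=rng)
        df = res.to_frame()
        assert np.all(np.diff(df["onset_s"]) > 0)
        assert df["onset_s"].iloc[-1] < 600.0
        # cumulative microlapse bookkeeping matches per-trial counts
        assert res.state.n_ml == df["n_microlapses"].sum()
        # session clock is consistent: last onset + its RT <= recorded final time
        assert res.state.t * 60.0 <= 600.0 + 30.0 + 1.0

    def test_gamma_variant_requires_zeta(self, rng, gamma2_params):
        with pytest.raises(ParameterError):
            simulate_session("gamma2", gamma2_params, rng=rng)

    def test_short_zeta_series_extended_with_warning(self, rng, gamma2_params):
        with pytest.warns(UserWarning, match="zeta series shorter"):
            res = simulate_session("gamma2", gamma2_params,
                                   zeta_series=np.ones(3), rng=rng)
        assert res.n_trials > 3

    def test_fatigue_decrement_at_fitted_values(self, cmf_params):
        """Lapse proportion grows from the first to the last 2-min bin."""
        lapses = np.zeros(5)
        counts = np.zeros(5)
        for i in range(40):
            df = simulate_session("cmf", cmf_params,
                                  rng=np.random.default_rng(1000 + i)).to_frame()
            df = df[df["rt_ms"].notna()]
            b = np.minimum(df["onset_s"] // 120, 4).astype(int)
            np.add.at(counts, b, 1)
            np.add.at(lapses, b, (df["response"] == "lapse").to_numpy())
        rate = lapses / counts
        assert rate[4] > 2.0 * rate[0]

    def test_threshold_decline_compensates_sleep_attacks(self):
        """kappa < 0 lowers the threshold with time and prevents stalls."""
        def total_sleep(kappa):
            n = 0
            for i in range(30):
                params = ModelParams(variant="cmf", upsilon=2.6, lambda_ml=0.9,
                                     phi=0.057, rho=-0.3, kappa=kappa)
                df = simulate_session("cmf", params,
                                      rng=np.random.default_rng(2000 + i)).to_frame()
                n += int((df["response"] == "sleep_attack").sum())
            return n

        assert total_sleep(-0.15) <= total_sleep(0.0)

    def test_end_spurt_lowers_late_lapses(self, gamma2_params):
        """Rising late motivation yields fewer late-bin lapses than falling."""
        def late_lapse_rate(zeta_end):
            lapses = trials = 0
            for i in range(30):
                z = np.linspace(1.0, zeta_end, 120)
                df = simulate_session("gamma2", gamma2_params, zeta_series=z,
                                      rng=np.random.default_rng(3000 + i)).to_frame()
                late = df[(df["onset_s"] >= 480) & df["rt_ms"].notna()]
                lapses += int((late["response"] == "lapse").sum())
                trials += len(late)
            return lapses / trials

        assert late_lapse_rate(1.3) < late_lapse_rate(0.7)


class TestSimulateCohort:
    def test_cohort_shape_and_ids(self, rng, cmf_params):
        res = simulate_cohort(5, lambda r: cmf_params, "cmf", rng=rng)
        assert len(res) == 5
        assert len({r.subject for r in res}) == 5

    def test_point_mass_sampler_shares_params(self, rng, cmf_params):
        res = simulate_cohort(3, lambda r: cmf_params, "cmf", rng=rng)
        assert all(r.params == cmf_params for r in res)

    def test_lapse_rate_increases_with_rho_magnitude(self):
        def cohort_lapse(rho):
            total = lapse = 0
            for i in range(12):
                params = ModelParams(variant="cmf", upsilon=3.2, lambda_ml=0.9,
                                     phi=0.057, rho=rho, kappa=-0.05)
                df = simulate_session("cmf", params,
                                      rng=np.random.default_rng(4000 + i)).to_frame()
                ok = df["rt_ms"].notna()
                total += int(ok.sum())
                lapse += int((df.loc[ok, "response"] == "lapse").sum())
            return lapse / total

        rates = [cohort_lapse(rho) for rho in (-0.05, -0.3, -0.6)]
        assert rates[0] < rates[1] < rates[2]
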