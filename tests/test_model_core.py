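"""Unit and property tests for the utility/threshold/selection equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import logistic

from pvtfatigue.model_core import (
    MICROLAPSE,
    ModelParams,
    ParameterError,
    SelectionContext,
    cmf_threshold,
    cmf_utility,
    gamma_utility,
    microlapse_probability,
    resolve_conflict,
    sample_utility_noise,
    selection_probabilities,
)


class TestUtilityEquations:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((3.82, 0.88, 0, 0, -0.20), 3.82),            # N=0, t=0 forces U = upsilon
            ((1.0, 0.5, 2, 0, -0.5), 0.25),               # lambda^2 alone
            ((1.0, 0.98, 0, 10, -0.05), math.exp(-0.05 * math.log(11.0))),
        ],
    )
    def test_cmf_utility_examples(self, args, expected):
        assert cmf_utility(*args) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((2.0, 0, -0.15), 2.0),
            ((2.0, 10, -0.01), 2.0 * math.exp(-0.01 * math.log(11.0))),
            ((2.0, 10, 0), 2.0),
        ],
    )
    def test_cmf_threshold_examples(self, args, expected):
        assert cmf_threshold(*args) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((4.15, 0.93, 0, 1.0), 4.15),
            ((4.15, 0.93, 3, 1.2), 4.15 * 0.93**3 * 1.2),
            ((1.0, 0.9, 0, 0.0), 0.0),
        ],
    )
    def test_gamma_utility_examples(self, args, expected):
        assert gamma_utility(*args) == pytest.approx(expected, rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (cmf_utility, (-1.0, 0.9, 0, 0, -0.1)),
            (cmf_utility, (1.0, 1.5, 0, 0, -0.1)),
            (cmf_utility, (1.0, 0.9, -1, 0, -0.1)),
            (cmf_threshold, (-2.0, 0, -0.1)),
            (gamma_utility, (1.0, 0.9, 0, -0.5)),
        ],
    )
    def test_domain_violations_raise(self, fn, args):
        with pytest.raises(ParameterError):
            fn(*args)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        upsilon=st.floats(0.1, 10.0),
        lam=st.floats(0.1, 0.999),
        t=st.floats(0.0, 30.0),
        rho=st.floats(-0.9, -0.01),
        n=st.integers(0, 20),
    )
    def test_cmf_utility_strictly_decreasing_in_nml_and_t(self, upsilon, lam, t, rho, n):
        u = cmf_utility(upsilon, lam, n, t, rho)
        assert cmf_utility(upsilon, lam, n + 1, t, rho) < u
        assert cmf_utility(upsilon, lam, n, t + 1.0, rho) < u

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        upsilon=st.floats(0.1, 10.0),
        lam=st.floats(0.1, 1.0),
        n=st.integers(0, 10),
        rho=st.floats(-0.9, 0.0),
    )
    def test_gamma_at_unit_zeta_equals_cmf_at_t0(self, upsilon, lam, n, rho):
        assert gamma_utility(upsilon, lam, n, 1.0) == pytest.approx(
            cmf_utility(upsilon, lam, n, 0.0, rho), rel=1e-12
        )


class TestUtilityNoise:
    def test_zero_scale_degenerates(self, rng):
        assert np.all(sample_utility_noise(0.0, 100, rng) == 0.0)

    def test_variance_matches_logistic(self, rng):
        draws = sample_utility_noise(1.0, 10**6, rng)
        target = math.pi**2 / 3.0
        se = math.sqrt(2.0) * target / math.sqrt(10**6)  # approx SE of sample var
        assert abs(draws.var() - target) < 3 * se * 2  # kurtosis margin

    def test_symmetry_at_zero(self, rng):
        draws = sample_utility_noise(0.5, 10**6, rng)
        p = (draws < 0).mean()
        assert abs(p - 0.5) < 3 * 0.5 / 1000.0

    def test_negative_scale_raises(self, rng):
        with pytest.raises(ParameterError):
            sample_utility_noise(-0.1, 10, rng)


class TestSelection:
    def test_equal_utilities_split_evenly(self):
        ctx = SelectionContext(utilities=(1.0, 1.0), threshold=0.0, s=0.3)
        probs, _ = selection_probabilities(ctx)
        assert probs == pytest.approx([0.5, 0.5])

    def test_single_above_threshold_takes_all(self):
        ctx = SelectionContext(utilities=(3.0, 1.0), threshold=2.0, s=0.3)
        probs, _ = selection_probabilities(ctx)
        assert probs == pytest.approx([1.0, 0.0])

    def test_softmax_hand_value(self):
        ctx = SelectionContext(utilities=(1.0, 2.0), threshold=0.0, s=0.5)  # 2s = 1
        probs, _ = selection_probabilities(ctx)
        assert probs == pytest.approx([1 / (1 + math.e), math.e / (1 + math.e)], rel=1e-12)

    def test_probabilities_sum_to_one_over_J(self, rng):
        for _ in range(50):
            k = rng.integers(1, 6)
            u = rng.uniform(0.0, 5.0, size=k)
            ctx = SelectionContext(utilities=u, threshold=2.0, s=rng.uniform(0.05, 1.0))
            probs, p_ml = selection_probabilities(ctx)
            if ctx.above_threshold.size:
                assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            else:
                assert p_ml == 1.0
            assert np.all(probs >= 0.0)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ParameterError):
            SelectionContext(utilities=(), threshold=0.0, s=0.1)


class TestResolveConflict:
    def test_deterministic_single_candidate(self, rng):
        ctx = SelectionContext(utilities=(3.0,), threshold=2.0, s=0.0)
        assert all(resolve_conflict(ctx, rng) == 0 for _ in range(20))

    def test_deterministic_starvation(self, rng):
        ctx = SelectionContext(utilities=(1.0, 1.5), threshold=2.0, s=0.0)
        assert all(resolve_conflict(ctx, rng) == MICROLAPSE for _ in range(20))

    def test_tie_break_lowest_index_flagged(self, rng):
        ctx = SelectionContext(utilities=(3.0, 3.0), threshold=2.0, s=0.0)
        with pytest.warns(UserWarning, match="tie"):
            assert resolve_conflict(ctx, rng) == 0

    def test_microlapse_frequency_matches_cdf_product(self, rng):
        # mixed context: one candidate below, one above the threshold
        ctx = SelectionContext(utilities=(1.8, 2.2), threshold=2.0, s=0.25)
        n = 200_000
        hits = sum(resolve_conflict(ctx, rng) == MICROLAPSE for _ in range(n))
        expected = float(np.prod(logistic.cdf((2.0 - np.array([1.8, 2.2])) / 0.25)))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se
        assert microlapse_probability(ctx) == pytest.approx(expected, rel=1e-12)

    def test_conditional_selection_matches_softmax(self, rng):
        # all candidates above threshold: conditional law is the Eq-1 soft-max
        ctx = SelectionContext(utilities=(2.6, 3.0), threshold=2.0, s=0.25)
        n = 200_000
        outcomes = np.array([resolve_conflict(ctx, rng) for _ in range(n)])
        fired = outcomes[outcomes != MICROLAPSE]
        probs, _ = selection_probabilities(ctx)
        p_hat = (fired == 1).mean()
        se = math.sqrt(probs[1] * (1 - probs[1]) / fired.size)
        assert abs(p_hat - probs[1]) < 3 * se


class TestModelParams:
    def test_bounds_enforced_at_construction(self):
        with pytest.raises(ParameterError, match="phi"):
            ModelParams(variant="cmf", upsilon=3.0, lambda_ml=0.9, phi=0.5)
        with pytest.raises(ParameterError, match="rho"):
            ModelParams(variant="cmf", upsilon=3.0, lambda_ml=0.9, phi=0.05, rho=-1.5)

    def test_gamma_variant_rejects_time_penalties(self):
        with pytest.raises(ParameterError):
            ModelParams(variant="gamma2", upsilon=3.0, lambda_ml=0.9, phi=0.05, rho=-0.1)

    def test_free_param_counts(self):
        cmf = ModelParams(variant="cmf", upsilon=3.0, lambda_ml=0.9, phi=0.05,
                          rho=-0.1, kappa=-0.1)
        g2 = ModelParams(variant="gamma2", upsilon=3.0, lambda_ml=0.9, phi=0.05)
        assert cmf.n_free == 5
        assert g2.n_free == 3
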