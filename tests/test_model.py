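"""Observer-model unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recalib.model import (
    CELLS,
    CellData,
    ConditionParams,
    GroupParams,
    ParticipantParams,
    condition_params,
    count_parameters,
    design_matrix,
    detection_probability,
    effects_code,
    joint_log_likelihood,
    loglik_grad_internal,
    loglik_internal,
    participant_loglik,
    response_probability,
)


def _flat_params(**kw):
    base = dict(tau_bar=150.0, delta_bar=311.0, sigmaL_bar=60.0, m_bar=0.0, lapse=0.02)
    base.update(kw)
    return ParticipantParams(**base)


class TestEffectsCoding:
    def test_convention(self):
        assert effects_code("simultaneity", "visual", "lag0") == (-0.5, -0.5, -0.5)
        assert effects_code("agency", "auditory", "lag150") == (0.5, 0.5, 0.5)

    def test_balanced(self):
        codes = np.array([effects_code(*c) for c in CELLS])
        assert np.allclose(codes.sum(axis=0), 0.0)
        D = design_matrix()
        assert np.allclose(D.sum(axis=0), 0.0)
        assert set(np.abs(D[:, 3:6]).ravel()) == {0.25}
        assert set(np.abs(D[:, 6]).ravel()) == {0.125}

    def test_unknown_level_fatal(self):
        with pytest.raises(ValueError, match="maybe"):
            effects_code("simultaneity", "maybe", "lag0")


class TestConditionParams:
    def test_null_betas_return_grand_means_everywhere(self):
        p = _flat_params()
        for cell in CELLS:
            cp = condition_params(p, effects_code(*cell))
            assert cp.tau == pytest.approx(150.0)
            assert cp.delta == pytest.approx(311.0)
            assert cp.sigmaL == pytest.approx(60.0)
            assert cp.m == pytest.approx(0.0)

    def test_additive_tau_effect(self):
        p = _flat_params(beta_tau=np.array([0, 0, 34.0, 0, 0, 0, 0]))
        lag0 = condition_params(p, effects_code("agency", "visual", "lag0"))
        lag150 = condition_params(p, effects_code("agency", "visual", "lag150"))
        assert lag0.tau == pytest.approx(150 - 17)
        assert lag150.tau == pytest.approx(150 + 17)
        assert lag150.tau - lag0.tau == pytest.approx(34.0)

    def test_multiplicative_delta_effect(self):
        # delta_bar 311, lag coefficient 0.2: cells at 311 e^{+-0.1}
        p = _flat_params(beta_delta=np.array([0, 0, 0.2, 0, 0, 0, 0]))
        lag0 = condition_params(p, effects_code("simultaneity", "visual", "lag0"))
        lag150 = condition_params(p, effects_code("simultaneity", "visual", "lag150"))
        assert lag150.delta == pytest.approx(311 * math.exp(0.1), rel=1e-12)
        assert lag0.delta == pytest.approx(311 * math.exp(-0.1), rel=1e-12)
        assert lag150.delta == pytest.approx(343.7, abs=0.05)
        assert lag0.delta == pytest.approx(281.4, abs=0.05)


class TestDetectionProbability:
    def test_standard_normal_window(self):
        # criteria at -1 and +1 with unit noise: Phi(1) - Phi(-1)
        cp = ConditionParams(tau=0.0, delta=2.0, sigmaL=1.0, m=0.0)
        expected = stats.norm.cdf(1) - stats.norm.cdf(-1)
        assert detection_probability(0.0, cp) == pytest.approx(expected, abs=1e-12)
        assert detection_probability(0.0, cp) == pytest.approx(0.6827, abs=5e-5)

    def test_degenerate_and_tails(self):
        cp = ConditionParams(tau=0.0, delta=1e-12, sigmaL=1.0, m=0.0)
        assert detection_probability(0.0, cp) == pytest.approx(0.0, abs=1e-9)
        cp = ConditionParams(tau=0.0, delta=100.0, sigmaL=10.0, m=0.3)
        assert detection_probability(1e7, cp) == pytest.approx(0.0, abs=1e-12)
        assert detection_probability(-1e7, cp) == pytest.approx(0.0, abs=1e-12)

    def test_never_negative_with_unequal_flanks(self):
        cp = ConditionParams(tau=0.0, delta=50.0, sigmaL=5.0, m=2.0)
        rsa = np.linspace(-2000, 2000, 4001)
        p = detection_probability(rsa, cp)
        assert np.all(p >= 0.0) and np.all(p <= 1.0)

    def test_integrates_to_delta_in_box_limit(self):
        # sigmaL << delta, m = 0: the window tends to an indicator of
        # width delta, so the integral over rsa approaches delta
        cp = ConditionParams(tau=20.0, delta=300.0, sigmaL=3.0, m=0.0)
        rsa = np.linspace(-1000, 1000, 200001)
        integral = np.trapezoid(detection_probability(rsa, cp), rsa)
        assert integral == pytest.approx(300.0, rel=0.01)


class TestResponseProbability:
    def test_examples(self):
        assert response_probability(0.9, 0.02) == pytest.approx(0.884)
        assert response_probability(0.3, 0.0) == pytest.approx(0.3)
        assert response_probability(0.123, 0.5) == pytest.approx(0.5)

    @given(p=st.floats(0, 1), lapse=st.floats(0, 0.499))
    @settings(deadline=None, derandomize=True)
    def test_range_and_reflection(self, p, lapse):
        out = response_probability(p, lapse)
        assert lapse - 1e-12 <= out <= 1 - lapse + 1e-12
        # guessing treats yes and no symmetrically
        assert response_probability(1 - p, lapse) == pytest.approx(1 - out, abs=1e-12)

    def test_monte_carlo_oracle_small(self, rng):
        cp = ConditionParams(tau=150.0, delta=311.0, sigmaL=60.0, m=0.1)
        lapse = 0.03
        for rsa in (-100.0, 50.0, 150.0, 400.0):
            expected = response_probability(detection_probability(rsa, cp), lapse)
            draws = rng.random(100_000) < expected
            assert draws.mean() == pytest.approx(expected, abs=0.005)


def _cells_single(rsa, n, y, cond=0):
    k = len(rsa)
    return CellData(rsa, n, y, [cond] * k)


class TestParticipantLoglik:
    def test_binomial_pmf_oracle(self):
        # predicted probability 0.5 at rsa = tau (wide window, lapse 0.5 caps
        # everything at one half): log C(10,5) + 10 log 0.5
        p = _flat_params(lapse=0.4999999)
        cells = _cells_single([150.0], [10], [5])
        expected = math.log(math.comb(10, 5)) + 10 * math.log(0.5)
        assert participant_loglik(p, cells) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(-1.402, abs=5e-4)

    def test_certain_outcome_zero(self):
        # probability ~1 in the middle of a huge window with no lapse
        p = _flat_params(tau_bar=0.0, delta_bar=1e5, sigmaL_bar=1.0, lapse=0.0)
        cells = _cells_single([0.0], [20], [20])
        assert participant_loglik(p, cells) == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_cell_doubles_contribution(self):
        p = _flat_params()
        one = _cells_single([100.0], [10], [4])
        two = _cells_single([100.0, 100.0], [10, 10], [4, 4])
        assert participant_loglik(p, two) == pytest.approx(
            2 * participant_loglik(p, one), rel=1e-12
        )

    def test_zero_probability_with_successes_is_neg_inf(self):
        p = _flat_params(lapse=0.0)
        cells = _cells_single([-5000.0], [10], [3])  # far tail, p = 0
        assert participant_loglik(p, cells) == -np.inf

    def test_analytic_gradient_matches_finite_differences(self, rng):
        p = _flat_params(beta_tau=rng.normal(0, 10, 7))
        rsa = np.array([-200.0, -50.0, 0.0, 100.0, 250.0, 450.0] * 4)
        cond = np.repeat([0, 3, 5, 7], 6)
        n = np.full(24, 12)
        y = rng.integers(0, 13, 24)
        cells = CellData(rsa, n, y, cond)
        x = p.to_internal() + rng.normal(0, 0.05, 33)
        _, grad = loglik_grad_internal(x, cells)
        eps = 1e-6
        for j in range(33):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            num = (loglik_internal(xp, cells) - loglik_internal(xm, cells)) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestJointLogLikelihood:
    def test_gaussian_mode_density(self):
        # one participant exactly at the group means: the group term is the
        # summed log density at the mode of each (transformed) Gaussian
        group = GroupParams(mean=np.zeros(32), sd=np.full(32, 2.0), lapse_mean=0.0)
        x = np.zeros(33)
        p = ParticipantParams.from_internal(x)
        cells = _cells_single([0.0], [10], [5])
        from recalib.model import LAPSE_GROUP_SD

        expected_group = (
            32 * stats.norm.logpdf(0, 0, 2.0)
            + stats.norm.logpdf(0, 0, LAPSE_GROUP_SD)
        )
        total = joint_log_likelihood(group, {"a": p}, {"a": cells})
        assert total == pytest.approx(
            participant_loglik(p, cells) + expected_group, abs=1e-9
        )

    def test_flat_hyperprior_limit(self):
        # as the group sds grow, the joint objective reduces to the data
        # log likelihood plus a participant-independent constant
        p = _flat_params()
        cells_a = _cells_single([0.0, 100.0], [10, 10], [2, 7])
        cells_b = _cells_single([0.0, 100.0], [10, 10], [5, 5])
        big = GroupParams(mean=np.zeros(32), sd=np.full(32, 1e8), lapse_mean=0.0)
        ja = joint_log_likelihood(big, {"a": p}, {"a": cells_a})
        jb = joint_log_likelihood(big, {"a": p}, {"a": cells_b})
        assert ja - jb == pytest.approx(
            participant_loglik(p, cells_a) - participant_loglik(p, cells_b), abs=1e-6
        )

    def test_missing_participant_fatal(self):
        group = GroupParams(mean=np.zeros(32), sd=np.ones(32), lapse_mean=0.0)
        with pytest.raises(ValueError, match="missing"):
            joint_log_likelihood(group, {}, {"a": _cells_single([0.0], [1], [0])})


class TestCountParameters:
    @pytest.mark.parametrize(
        "n, expected",
        [(48, (1584, 65, 1649)), (1, (33, 65, 98)), (10, (330, 65, 395))],
    )
    def test_counts(self, n, expected):
        assert count_parameters(n) == expected

    def test_individual_block_divisible(self):
        for n in (1, 7, 48):
            ind, grp, total = count_parameters(n)
            assert (total - grp) % 33 == 0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            count_parameters(0)


class TestParameterContainers:
    def test_internal_roundtrip(self, rng):
        p = ParticipantParams(
            tau_bar=123.0, delta_bar=280.0, sigmaL_bar=55.0, m_bar=-0.2, lapse=0.07,
            beta_tau=rng.normal(0, 20, 7), beta_delta=rng.normal(0, 0.2, 7),
            beta_sigma=rng.normal(0, 0.2, 7), beta_m=rng.normal(0, 0.2, 7),
        )
        q = ParticipantParams.from_internal(p.to_internal())
        assert q.tau_bar == pytest.approx(p.tau_bar)
        assert q.delta_bar == pytest.approx(p.delta_bar)
        assert q.lapse == pytest.approx(p.lapse, abs=1e-9)
        assert np.allclose(q.beta_tau, p.beta_tau)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticipantParams(tau_bar=0, delta_bar=-1, sigmaL_bar=1, m_bar=0, lapse=0.02)
        with pytest.raises(ValueError):
            ParticipantParams(tau_bar=0, delta_bar=1, sigmaL_bar=1, m_bar=0, lapse=0.6)
        with pytest.raises(ValueError):
            GroupParams(mean=np.zeros(32), sd=np.zeros(32), lapse_mean=0.0)

    def test_group_vector_roundtrip(self):
        g = GroupParams(mean=np.arange(32) * 0.1, sd=np.ones(32) * 0.5, lapse_mean=-3.0)
        h = GroupParams.from_vector(g.to_vector())
        assert np.allclose(h.mean, g.mean) and np.allclose(h.sd, g.sd)
        assert g.to_vector().size == 65
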