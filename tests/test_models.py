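"""Confounded logistic models: marginals, ATE, strength curves, scenarios."""

import numpy as np
import pytest
from scipy.special import expit

from mrbounds import (
    ContinuousExposureModel,
    ExposureModel,
    OutcomeModel,
    all_instrument_marginals,
    ate,
    dichotomized_experiment,
    exposure_prob,
    instrument_strength,
    iv_inequality_check,
    model_marginals,
    scenario_gammas,
    smallest_gamma_excluding_zero,
    st_to_gamma1,
    two_sample_bounds,
)
from mrbounds.models import _st_of_gamma1


def _single(gamma1, gammaU, gamma0=None):
    return ExposureModel(
        gamma0=-gamma1 if gamma0 is None else gamma0,
        gammas=np.array([gamma1]),
        gammaU=gammaU,
    )


class TestExposureProb:
    def test_no_confounding_is_plain_expit(self):
        em = _single(0.7, 0.0, gamma0=-0.2)
        for z in range(3):
            assert exposure_prob(em, [z]) == pytest.approx(expit(-0.2 + 0.7 * z))

    def test_null_instrument_flat(self):
        em = ExposureModel(gamma0=0.3, gammas=np.array([0.0]), gammaU=1.5)
        probs = [exposure_prob(em, [z]) for z in range(3)]
        assert instrument_strength(probs) == pytest.approx(0.0, abs=1e-14)

    def test_confounding_attenuates_strength(self):
        assert _st_of_gamma1(1.5, 2.0) < _st_of_gamma1(1.5, 0.1)

    def test_quadrature_matches_monte_carlo(self, rng):
        em = _single(1.0, 1.3)
        u = rng.standard_normal(500_000)
        mc = expit(-1.0 + 1.0 * 2 + 1.3 * u).mean()
        assert exposure_prob(em, [2]) == pytest.approx(mc, abs=2e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            exposure_prob(_single(1.0, 0.5), [1, 2])


class TestAte:
    def test_null_exposure_effect(self):
        assert ate(OutcomeModel(beta0=0.3, betaX=0.0, betaU=1.0)) == pytest.approx(0.0)

    def test_no_confounding_closed_form(self):
        om = OutcomeModel(beta0=-0.2, betaX=0.9, betaU=0.0)
        assert ate(om) == pytest.approx(expit(0.7) - expit(-0.2), abs=1e-12)

    def test_symmetric_intercept_is_odd_in_effect(self):
        for bx in (0.5, 1.3):
            pos = ate(OutcomeModel(beta0=-bx / 2, betaX=bx, betaU=0.7))
            neg = ate(OutcomeModel(beta0=bx / 2, betaX=-bx, betaU=0.7))
            assert pos == pytest.approx(-neg, abs=1e-12)

    def test_pleiotropy_requires_genotype_dist(self):
        om = OutcomeModel(beta0=0.0, betaX=1.0, betaU=1.0, betaZ=0.3)
        with pytest.raises(ValueError):
            ate(om)
        assert np.isfinite(ate(om, [0.25, 0.5, 0.25]))


class TestModelMarginals:
    def test_no_exposure_or_direct_effect_flattens_outcome(self):
        em = _single(1.2, 0.8)
        om = OutcomeModel(beta0=-0.1, betaX=0.0, betaU=0.9)
        m = model_marginals(em, om)
        assert np.ptp(m.p_y) == pytest.approx(0.0, abs=1e-12)

    def test_unconfounded_closed_form(self):
        em = _single(0.9, 0.0)
        om = OutcomeModel(beta0=-0.4, betaX=0.8, betaU=0.0)
        m = model_marginals(em, om)
        for z in range(3):
            px = expit(-0.9 + 0.9 * z)
            expected = expit(0.4) * px + expit(-0.4) * (1 - px)
            assert m.p_y[z] == pytest.approx(expected, abs=1e-12)

    def test_valid_instrument_bounds_cover_ate(self, rng):
        # the central containment property under the core IV assumptions
        for _ in range(20):
            g1 = rng.uniform(0.2, 3.0)
            em = _single(g1, rng.uniform(0.0, 2.0))
            om = OutcomeModel(
                beta0=rng.uniform(-1, 1),
                betaX=rng.uniform(-2, 2),
                betaU=rng.uniform(0.0, 2.0),
            )
            m = model_marginals(em, om)
            b = two_sample_bounds(m)
            assert iv_inequality_check(m).passed
            assert not b.crossed
            assert b.contains(ate(om), tol=1e-9)

    def test_monte_carlo_agrees_with_quadrature_for_shared_instrument(self):
        # p=2 with the second instrument inert reduces to the p=1 model
        em2 = ExposureModel(gamma0=-1.0, gammas=np.array([1.0, 0.0]), gammaU=0.5)
        om = OutcomeModel(beta0=-0.5, betaX=1.0, betaU=0.5)
        mc = model_marginals(em2, om, instrument_index=0, mc_n=400_000, seed=3)
        exact = model_marginals(_single(1.0, 0.5), om)
        np.testing.assert_allclose(mc.p_x, exact.p_x, atol=3e-3)
        np.testing.assert_allclose(mc.p_y, exact.p_y, atol=3e-3)

    def test_all_instruments_matches_per_instrument_route(self):
        gammas = scenario_gammas(1, 4)
        em = ExposureModel(gamma0=-gammas.sum(), gammas=gammas, gammaU=0.5)
        om = OutcomeModel(beta0=-0.25, betaX=0.5, betaU=0.5)
        shared = all_instrument_marginals(em, om, mc_n=300_000, seed=9)
        solo = model_marginals(em, om, instrument_index=3, mc_n=300_000, seed=10)
        np.testing.assert_allclose(shared[3].p_x, solo.p_x, atol=4e-3)
        np.testing.assert_allclose(shared[3].p_y, solo.p_y, atol=4e-3)


class TestStrengthCurve:
    def test_monotone_and_continuous(self):
        gammas = np.linspace(0.1, 5.0, 25)
        sts = [_st_of_gamma1(g, 1.0) for g in gammas]
        assert np.all(np.diff(sts) > 0)
        assert sts[0] < 0.05

    def test_inverse_round_trip(self):
        for gu in (0.1, 1.0, 2.0):
            g1 = st_to_gamma1(0.4, gu)
            assert _st_of_gamma1(g1, gu) == pytest.approx(0.4, abs=1e-9)

    def test_small_target_gives_small_coefficient(self):
        assert st_to_gamma1(0.01, 0.5) < 0.05

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            st_to_gamma1(0.999, 2.0, bracket=(1e-9, 1.0))


class TestSmallestGamma:
    def test_null_effect_never_qualifies(self):
        om = OutcomeModel(beta0=0.0, betaX=0.0, betaU=1.0)
        assert smallest_gamma_excluding_zero(om, gammaU=1.0) is None

    def test_monotone_in_effect_size(self):
        oms = [
            OutcomeModel(beta0=-bx / 2, betaX=bx, betaU=0.5) for bx in (1.0, 2.0, 3.0)
        ]
        gammas = [smallest_gamma_excluding_zero(om, gammaU=0.5) for om in oms]
        assert all(g is not None for g in gammas)
        assert gammas[0] > gammas[1] > gammas[2]

    def test_monotone_in_confounding(self):
        om = OutcomeModel(beta0=-1.0, betaX=2.0, betaU=1.0)
        weak = smallest_gamma_excluding_zero(om, gammaU=0.2)
        strong = smallest_gamma_excluding_zero(om, gammaU=2.0)
        assert weak is not None and strong is not None and weak < strong

    def test_result_actually_qualifies(self):
        om = OutcomeModel(beta0=-1.0, betaX=2.0, betaU=1.0)
        g1 = smallest_gamma_excluding_zero(om, gammaU=1.0)
        em = _single(g1, 1.0)
        b = two_sample_bounds(model_marginals(em, om))
        assert b.lower > 0 and b.contains(ate(om), tol=1e-9)


class TestScenarioGammas:
    def test_printed_sequences(self):
        np.testing.assert_allclose(scenario_gammas(1, 10), np.linspace(0, 0.2, 10))
        s3 = scenario_gammas(3, 10)
        np.testing.assert_allclose(s3[:9], np.linspace(0, 0.01, 9))
        assert s3[9] == pytest.approx(0.2)
        assert scenario_gammas(4, 50).max() == pytest.approx(4.0)
        assert scenario_gammas(2, 10).min() == pytest.approx(1.0)

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            scenario_gammas(5, 10)


class TestDichotomized:
    def test_null_effect_covers_zero(self):
        cm = ContinuousExposureModel(gamma1=1.0, gammaU=1.0)
        om = OutcomeModel(beta0=0.0, betaX=0.0, betaU=1.0)
        _, b, rep = dichotomized_experiment(cm, om, n=200_000, seed=4)
        assert b.covers_zero and rep.inferred_sign == 0 and rep.consistent

    def test_weak_instrument_near_trivial_bounds(self):
        cm = ContinuousExposureModel(gamma1=0.0, gammaU=1.0)
        om = OutcomeModel(beta0=0.0, betaX=1.0, betaU=1.0)
        m, b, _ = dichotomized_experiment(cm, om, n=400_000, seed=5)
        assert instrument_strength(m.p_x) < 0.01
        assert b.length > 1.95

    @pytest.mark.parametrize("betaX", [-2.0, 2.0])
    def test_strong_case_recovers_sign(self, betaX):
        cm = ContinuousExposureModel(gamma1=2.0, gammaU=1.0)
        om = OutcomeModel(beta0=0.0, betaX=betaX, betaU=1.0)
        _, b, rep = dichotomized_experiment(cm, om, n=600_000, seed=6)
        assert rep.inferred_sign == rep.true_sign == np.sign(betaX)
        assert rep.consistent
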