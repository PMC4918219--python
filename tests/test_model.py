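"""Closed-form operations against hand-derived and oracle-frozen values.

Expected numbers were computed from direct arithmetic on the default
parameters and cross-checked against the numerical grid oracle
(tests/test_oracle_equivalence.py exercises the equivalence broadly).
"""

import math

import numpy as np
import pytest

from swimodel import (
    DensityHypothesis,
    ModelParams,
    density_prior_covariance,
    haptic_likelihood_given_hypothesis,
    hypothesis_posterior,
    map_lift,
    map_no_lift,
    naive_single_prior_estimate,
    posterior_mean_w,
    posterior_w_given_hypothesis,
    visual_log_volume_mean,
    weight_prior_under_hypothesis,
)

R1, R2, R3 = DensityHypothesis.R1, DensityHypothesis.R2, DensityHypothesis.R3


class TestVisualMean:
    def test_equal_volumes_give_zero(self, default_params):
        assert visual_log_volume_mean(442.45, 442.45, default_params) == 0.0

    def test_compressed_log_ratio(self, default_params):
        v = visual_log_volume_mean(131.10, 3539.61, default_params)
        assert v == pytest.approx(0.704 * math.log(131.10 / 3539.61), abs=1e-12)
        assert v == pytest.approx(-2.3203, abs=5e-4)

    def test_identity_exponent(self):
        p = ModelParams(volume_exponent=1.0)
        assert visual_log_volume_mean(math.e, 1.0, p) == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self, default_params):
        a = visual_log_volume_mean(131.10, 442.45, default_params)
        b = visual_log_volume_mean(442.45, 131.10, default_params)
        assert a == -b

    @pytest.mark.parametrize("va,vb", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_volume_rejected(self, va, vb, default_params):
        with pytest.raises(ValueError):
            visual_log_volume_mean(va, vb, default_params)


class TestPriorStructure:
    def test_equal_density_prior_is_one_dimensional(self, default_params):
        cov = density_prior_covariance(R1, default_params)
        assert np.allclose(cov, [[0.85, 0.0], [0.0, 0.0]])

    def test_uncorrelated_unit_prior_is_identity(self):
        p = ModelParams(sigma_v2=1.0, sigma_d2=1.0, rho3=0.0)
        assert np.allclose(density_prior_covariance(R3, p), np.eye(2))

    def test_smaller_denser_covariance(self, default_params):
        cov = density_prior_covariance(R2, default_params)
        assert cov[0, 1] == pytest.approx(-0.95 * math.sqrt(0.85 * 1.2), abs=1e-12)
        assert cov[0, 1] == pytest.approx(-0.9595, abs=1e-4)
        # symmetric positive semidefinite
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12

    def test_correlation_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(rho2=-1.0001)

    def test_weight_prior_marginals(self, default_params):
        # Var(v + d) = sv2 + sd2 + 2 rho sv sd
        b1 = weight_prior_under_hypothesis(R1, default_params)
        assert (b1.mean, b1.variance) == (0.0, pytest.approx(0.85))
        b2 = weight_prior_under_hypothesis(R2, default_params)
        assert b2.variance == pytest.approx(0.13109406, abs=1e-7)
        b3 = weight_prior_under_hypothesis(R3, default_params)
        assert b3.variance == pytest.approx(3.96890594, abs=1e-7)

    def test_density_offset_shifts_smaller_denser_prior(self):
        p = ModelParams(mu_d_R2=math.log(10))
        assert weight_prior_under_hypothesis(R2, p).mean == pytest.approx(math.log(10))
        assert weight_prior_under_hypothesis(R3, p).mean == 0.0


class TestPerHypothesisPosterior:
    def test_symmetric_input_centered(self, default_params):
        for h in (R1, R2, R3):
            assert posterior_w_given_hypothesis(0.0, None, h, default_params).mean == 0.0

    def test_equal_density_expectation_follows_vision(self, default_params):
        b = posterior_w_given_hypothesis(-2.3203, None, R1, default_params)
        assert b.mean == pytest.approx(-2.3203)
        assert b.variance == pytest.approx(0.10)

    def test_smaller_denser_expectation_compensates(self, default_params):
        # k2 = 1 + rho2 sd/sv < 0: larger-looking pairs are expected near-equal weight
        b = posterior_w_given_hypothesis(-2.3203, None, R2, default_params)
        assert b.mean == pytest.approx(0.2987809, abs=1e-6)
        assert b.variance == pytest.approx(0.1186581, abs=1e-6)

    def test_larger_denser_expectation_amplifies(self, default_params):
        b = posterior_w_given_hypothesis(-2.3203, None, R3, default_params)
        assert b.mean == pytest.approx(-4.9393809, abs=1e-6)
        assert b.variance == pytest.approx(0.5701654, abs=1e-6)

    def test_haptic_update_is_precision_weighted(self, default_params):
        b = posterior_w_given_hypothesis(-2.3203, 0.0, R1, default_params)
        # (m/s2 + x/sx2) / (1/s2 + 1/sx2) with s2=0.1, sx2=0.5
        assert b.mean == pytest.approx(-2.3203 * 5 / 6, abs=1e-9)
        assert b.variance == pytest.approx(1 / 12, abs=1e-9)

    def test_posterior_mean_between_expectation_and_evidence(self, default_params):
        m0 = posterior_mean_w(-1.0, None, R1, default_params)
        m = posterior_mean_w(-1.0, 0.0, R1, default_params)
        assert m0 < m < 0.0

    def test_zero_inputs_give_zero_for_every_hypothesis(self, default_params):
        for h in (R1, R2, R3):
            assert posterior_mean_w(0.0, 0.0, h, default_params) == 0.0


class TestHapticLikelihoodAndArbitration:
    def test_likelihood_peaks_at_predicted_weight(self, default_params):
        y = -1.0
        m = posterior_w_given_hypothesis(y, None, R2, default_params).mean
        peak = haptic_likelihood_given_hypothesis(m, y, R2, default_params)
        for dx in (-0.5, -0.1, 0.1, 0.5):
            assert haptic_likelihood_given_hypothesis(m + dx, y, R2, default_params) < peak

    def test_equal_density_has_sharpest_prediction_at_origin(self, default_params):
        l1 = haptic_likelihood_given_hypothesis(0.0, 0.0, R1, default_params)
        l3 = haptic_likelihood_given_hypothesis(0.0, 0.0, R3, default_params)
        assert l1 == pytest.approx(1 / math.sqrt(2 * math.pi * 0.6), abs=1e-12)
        assert l1 > l3

    def test_missing_haptic_measurement_rejected(self, default_params):
        with pytest.raises(ValueError):
            haptic_likelihood_given_hypothesis(None, 0.0, R1, default_params)
        with pytest.raises(ValueError):
            hypothesis_posterior(None, 0.0, default_params)
        with pytest.raises(ValueError):
            map_lift(None, 0.0, default_params)

    def test_posterior_keeps_prior_under_equal_evidence(self):
        # identical predictive distributions for R2/R3 at y=0; R1 sharper,
        # so engineer exact equality with a symmetric two-sigma setup
        p = ModelParams(sigma_d2=0.0, prior_R=(0.8, 0.15, 0.05))
        post = hypothesis_posterior(0.0, 0.0, p)
        assert post == pytest.approx((0.8, 0.15, 0.05), abs=1e-12)

    def test_equal_density_wins_for_matched_objects(self, default_params):
        post = hypothesis_posterior(0.0, 0.0, default_params)
        assert post[0] >= 0.8
        assert sum(post) == pytest.approx(1.0, abs=1e-12)

    def test_smaller_denser_wins_for_discrepant_sizes(self, default_params):
        post = hypothesis_posterior(0.0, -2.3203, default_params)
        assert post[1] > 0.15  # exceeds its prior
        assert post[1] > 0.9


class TestMapEstimates:
    def test_no_lift_symmetric_zero(self, default_params):
        assert map_no_lift(0.0, default_params) == 0.0

    def test_no_lift_tracks_visual_volume_estimate(self, default_params):
        # expectation reports should match the visually estimated volume
        # relationship for the dominant equal-density hypothesis
        w = map_no_lift(-2.320251, default_params)
        assert w == pytest.approx(-2.320281, abs=1e-4)

    def test_lift_symmetric_zero(self, default_params):
        assert map_lift(0.0, 0.0, default_params) == 0.0

    def test_lift_positive_for_most_discrepant_pair(self, default_params):
        assert map_lift(0.0, -2.320251, default_params) == pytest.approx(0.24147, abs=1e-4)

    def test_naive_baseline_inverts_the_illusion(self, default_params):
        # the single "larger is heavier" prior predicts the larger object
        # to feel heavier (negative canonical value)
        w = naive_single_prior_estimate(0.0, -2.320251, default_params)
        assert w < 0
        assert w == pytest.approx(-2.320251 * 5 / 6, abs=1e-9)

    def test_naive_baseline_trivial_cases(self, default_params):
        assert naive_single_prior_estimate(0.0, 0.0, default_params) == 0.0
        assert naive_single_prior_estimate(0.3, 5.0, default_params,
                                           prior_variance=math.inf) == 0.3
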