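"""Wald ratio, correlated IVW, PC stabilization, OR conversion, pooling."""

import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.base import clone

from mrld.estimators import (
    ConditionNumberError,
    CorrelatedIVW,
    EstimationError,
    MREstimate,
    PCStabilizedIVW,
    WaldRatio,
    WeakInstrumentError,
    ivw_correlated,
    meta_fixed_effect,
    pc_ivw,
    to_odds_ratio,
    wald_ratio,
)
from tests.helpers import gls_oracle, make_harmonized, random_correlation


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,sy,theta,se", [
        (0.2, 0.1, 0.05, 0.5, 0.25),
        (1.0, 0.37, 0.12, 0.37, 0.12),
        (-0.2, 0.1, 0.05, -0.5, 0.25),
    ])
    def test_ratio_arithmetic(self, bx, by, sy, theta, se):
        est = wald_ratio(bx, by, sy)
        assert est.theta == pytest.approx(theta)
        assert est.se_theta == pytest.approx(se)

    def test_zero_exposure_beta_is_weak_instrument_error(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(0.0, 0.1, 0.05)


class TestCorrelatedIVW:
    def test_single_variant_reduces_to_wald(self):
        h = make_harmonized([0.2], [0.1], [0.05])
        est = ivw_correlated(h)
        w = wald_ratio(0.2, 0.1, 0.05)
        assert est.theta == pytest.approx(w.theta, abs=1e-14)
        assert est.se_theta == pytest.approx(w.se_theta, abs=1e-14)

    def test_identity_ld_matches_textbook_ivw_closed_form(self):
        h = make_harmonized([0.5, 0.25], [0.2, 0.05], [0.1, 0.1])
        est = ivw_correlated(h)
        assert est.theta == pytest.approx(0.36, abs=1e-12)
        assert est.se_theta == pytest.approx(0.1788854382, abs=1e-9)

    def test_hand_computed_gls_with_rho_half(self):
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        h = make_harmonized([0.5, 0.25], [0.2, 0.05], [0.1, 0.1], rho=rho)
        est = ivw_correlated(h)
        assert est.theta == pytest.approx(0.4, abs=1e-12)
        assert est.se_theta == pytest.approx(0.2, abs=1e-12)

    def test_identity_ld_equals_textbook_formula_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 20))
            x = rng.normal(0.1, 0.05, k)
            y = rng.normal(0, 0.05, k)
            se = rng.uniform(0.02, 0.2, k)
            est = CorrelatedIVW().fit(x, y, se_outcome=se)
            w = se**-2
            assert est.theta_ == pytest.approx(
                float(np.sum(w * x * y) / np.sum(w * x * x)), abs=1e-10)
            assert est.se_theta_ == pytest.approx(
                float(np.sum(w * x * x) ** -0.5), abs=1e-10)

    def test_invariant_under_allele_flip(self, rng):
        k = 6
        rho = random_correlation(rng, k)
        x = rng.normal(0.1, 0.05, k)
        y = rng.normal(0.02, 0.05, k)
        se = rng.uniform(0.02, 0.2, k)
        base = CorrelatedIVW().fit(x, y, se_outcome=se, ld=rho)
        signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
        flipped = CorrelatedIVW().fit(
            signs * x, signs * y, se_outcome=se,
            ld=rho * np.outer(signs, signs))
        assert flipped.theta_ == pytest.approx(base.theta_, abs=1e-12)
        assert flipped.se_theta_ == pytest.approx(base.se_theta_, abs=1e-12)

    def test_near_singular_covariance_directs_to_pc(self):
        rho = np.array([[1.0, 1.0 - 1e-10], [1.0 - 1e-10, 1.0]])
        h = make_harmonized([0.3, 0.3], [0.12, 0.12], [0.05, 0.05], rho=rho)
        with pytest.raises(ConditionNumberError, match="PCStabilized"):
            ivw_correlated(h)

    def test_pvalue_consistent_with_normal_formula(self, rng):
        h = make_harmonized(rng.normal(0.1, 0.05, 5), rng.normal(0, 0.05, 5),
                            rng.uniform(0.02, 0.2, 5))
        est = ivw_correlated(h)
        assert est.pvalue == pytest.approx(
            2 * norm.sf(abs(est.theta / est.se_theta)), abs=1e-12)

    def test_exposure_se_weighting_switch(self):
        h = make_harmonized([0.5, 0.25], [0.2, 0.05], [0.1, 0.1],
                            se_x=[0.02, 0.04])
        est = ivw_correlated(h, weights="exposure_se")
        theta, se = gls_oracle([0.5, 0.25], [0.2, 0.05], [0.02, 0.04], np.eye(2))
        assert est.theta == pytest.approx(theta, abs=1e-12)

    def test_sklearn_protocol(self):
        est = CorrelatedIVW(cond_max=1e6)
        assert clone(est).get_params()["cond_max"] == 1e6
        est.set_params(weights="outcome_se")
        est.fit([0.5, 0.25], [0.2, 0.05], se_outcome=[0.1, 0.1])
        np.testing.assert_allclose(est.predict([1.0, 2.0]), [0.36, 0.72])


class TestPCStabilized:
    def test_full_variance_equals_plain_gls_on_full_rank_input(self, rng):
        rho = random_correlation(rng, 3, shrink=0.3)
        h = make_harmonized(rng.normal(0.15, 0.03, 3), rng.normal(0.03, 0.02, 3),
                            rng.uniform(0.03, 0.08, 3), rho=rho)
        full = pc_ivw(h, variance_kept=1.0)
        plain = ivw_correlated(h)
        assert full.theta == pytest.approx(plain.theta, abs=1e-8)
        assert full.se_theta == pytest.approx(plain.se_theta, abs=1e-8)
        assert full.pc_k == 3

    def test_duplicated_variant_collapses_to_single_wald(self):
        rho = np.ones((2, 2))
        h = make_harmonized([0.3, 0.3], [0.12, 0.12], [0.05, 0.05], rho=rho)
        est = pc_ivw(h)
        w = wald_ratio(0.3, 0.12, 0.05)
        assert est.pc_k == 1
        assert est.theta == pytest.approx(w.theta, abs=1e-10)
        assert est.se_theta == pytest.approx(w.se_theta, abs=1e-10)

    def test_high_ld_block_estimate_near_pruned_subset(self, rng):
        # 50 variants in blocks of 5 at rho .95; compare against GLS on one
        # representative per block
        from mrld.simulate import SimulationConfig, make_ld_matrix
        cfg = SimulationConfig(n_variants=50, ld_structure="blocks",
                               ld_rho=0.95, block_size=5, seed=3)
        ld = make_ld_matrix(cfg)
        beta_x = rng.normal(0.15, 0.03, 50)
        theta_true = 0.25
        chol = np.linalg.cholesky(ld.r)
        se_y = np.full(50, 0.05)
        beta_y = theta_true * beta_x + se_y * (chol @ rng.standard_normal(50))
        h = make_harmonized(beta_x, beta_y, se_y, rho=ld.r)
        stabilized = pc_ivw(h, variance_kept=0.99)
        pruned = h.subset([h.variant_ids[i] for i in range(0, 50, 5)])
        ref = ivw_correlated(pruned)
        assert abs(stabilized.theta - ref.theta) < 2 * ref.se_theta

    def test_variance_kept_validation(self):
        h = make_harmonized([0.3, 0.2], [0.1, 0.05], [0.05, 0.05])
        with pytest.raises(ValueError):
            pc_ivw(h, variance_kept=0.0)
        with pytest.raises(ValueError):
            pc_ivw(h, variance_kept=1.5)

    def test_needs_at_least_two_variants(self):
        with pytest.raises(ValueError):
            pc_ivw(make_harmonized([0.3], [0.1], [0.05]))

    def test_unweighted_mode_runs(self, rng):
        rho = random_correlation(rng, 4, shrink=0.3)
        h = make_harmonized(rng.normal(0.15, 0.03, 4), rng.normal(0.03, 0.02, 4),
                            rng.uniform(0.03, 0.08, 4), rho=rho)
        est = PCStabilizedIVW(variance_kept=1.0, weighted=False).fit(
            h.beta_exposure, h.beta_outcome, se_outcome=h.se_outcome, ld=h.ld.r)
        plain = ivw_correlated(h)
        assert est.theta_ == pytest.approx(plain.theta, abs=1e-8)


class TestOddsRatio:
    def test_null_effect(self):
        rec = to_odds_ratio(MREstimate(0.0, 0.1, 1.0, 1, "wald"))
        assert rec.or_point == pytest.approx(1.0)
        assert rec.ci_low == pytest.approx(0.8220, abs=2e-4)
        assert rec.ci_high == pytest.approx(1.2166, abs=2e-4)

    def test_printed_ci_round_trip(self):
        # a published OR row "1.24 (1.01 to 1.51)" regenerates its endpoints
        # from the log-midpoint and the implied se; the point agrees with the
        # printed 1.24 to published rounding
        theta = (math.log(1.51) + math.log(1.01)) / 2
        se = (math.log(1.51) - math.log(1.01)) / (2 * 1.959964)
        est = MREstimate(theta, se, 2 * norm.sf(theta / se), 10, "ivw_correlated")
        rec = to_odds_ratio(est)
        assert rec.or_point == pytest.approx(1.24, abs=6e-3)
        assert rec.ci_low == pytest.approx(1.01, abs=1e-9)
        assert rec.ci_high == pytest.approx(1.51, abs=1e-9)

    def test_se_to_zero_limit_collapses_ci(self):
        rec = to_odds_ratio(MREstimate(0.2, 1e-12, 0.0, 1, "wald"))
        assert rec.ci_low == pytest.approx(rec.or_point, rel=1e-9)
        assert rec.ci_high == pytest.approx(rec.or_point, rel=1e-9)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            to_odds_ratio(MREstimate(0.0, 0.1, 1.0, 1, "wald"), level=1.2)


class TestMetaFixedEffect:
    def _e(self, theta, se, scale="log_odds"):
        return MREstimate(theta, se, 2 * norm.sf(abs(theta / se)), 5,
                          "ivw_correlated", trait_scale=scale)

    def test_single_estimate_unchanged(self):
        e = self._e(0.2, 0.1)
        assert meta_fixed_effect([e]) is e

    def test_equal_weight_average(self):
        pooled = meta_fixed_effect([self._e(0.2, 0.1), self._e(0.4, 0.1)])
        assert pooled.theta == pytest.approx(0.3)
        assert pooled.se_theta == pytest.approx(0.070711, abs=1e-6)

    def test_infinite_se_contributes_nothing(self):
        pooled = meta_fixed_effect([self._e(0.2, 0.1), self._e(5.0, math.inf)])
        assert pooled.theta == pytest.approx(0.2)
        assert pooled.se_theta == pytest.approx(0.1)

    def test_mixed_scales_rejected(self):
        with pytest.raises(EstimationError, match="mixed"):
            meta_fixed_effect([self._e(0.2, 0.1), self._e(0.1, 0.1, "continuous_sd")])


def test_gls_oracle_equivalence_small(rng):
    """Spot check against the explicit-inverse GLS reference."""
    for _ in range(50):
        k = int(rng.integers(1, 15))
        rho = random_correlation(rng, k)
        x = rng.normal(0.1, 0.05, k)
        y = rng.normal(0.02, 0.05, k)
        se = rng.uniform(0.02, 0.2, k)
        est = CorrelatedIVW().fit(x, y, se_outcome=se, ld=rho)
        theta, se_t = gls_oracle(x, y, se, rho)
        assert est.theta_ == pytest.approx(theta, abs=1e-10)
        assert est.se_theta_ == pytest.approx(se_t, abs=1e-10)


def test_wald_ratio_se_is_first_order_in_outcome_se_only():
    # doubling the outcome se doubles the estimate's se; exposure se is ignored
    a = wald_ratio(0.2, 0.1, 0.05)
    b = wald_ratio(0.2, 0.1, 0.10)
    assert b.se_theta == pytest.approx(2 * a.se_theta)
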