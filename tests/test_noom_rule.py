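"""Majority-rule decision rates: closed forms, oracle equivalence, thresholds."""

import numpy as np
import pytest

from typinfer import (
    Decision,
    InputDomainError,
    OutcomeDistribution,
    ResourceGuardError,
    classify_sample,
    delta_curve,
    delta_difference,
    enumerate_exact,
    majority_threshold,
    min_typicality_percent,
    omega_threshold,
    rule_rates,
)


def random_distribution(rng, k):
    """Random outcome distribution with a strictly modal representative."""
    while True:
        raw = rng.dirichlet(np.ones(k))
        order = np.argsort(raw)[::-1]
        probs = raw[order]
        if k == 1 or probs[0] > probs[1] + 1e-6:
            return OutcomeDistribution(tuple(probs))


class TestThresholdAndClassification:
    @pytest.mark.parametrize("m, expected", [(1, 1), (2, 2), (3, 2), (4, 3), (7, 4)])
    def test_strict_majority_threshold(self, m, expected):
        assert majority_threshold(m) == expected

    def test_threshold_rejects_nonpositive(self):
        with pytest.raises(InputDomainError):
            majority_threshold(0)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((3, 0), Decision.CORRECT),
            ((1, 2), Decision.INCORRECT),
            ((1, 1, 1), Decision.INCONCLUSIVE),
            ((2, 1), Decision.CORRECT),
        ],
    )
    def test_classification(self, counts, expected):
        assert classify_sample(counts, 3) is expected

    def test_counts_must_sum_to_m(self):
        with pytest.raises(InputDomainError):
            classify_sample((1, 1), 3)


class TestDistributionInvariants:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(InputDomainError):
            OutcomeDistribution((0.85, 0.15, 0.05))

    def test_representative_must_be_modal(self):
        with pytest.raises(InputDomainError):
            OutcomeDistribution((0.4, 0.4, 0.2))

    def test_omega_is_total_outlier_mass(self):
        dist = OutcomeDistribution((0.8, 0.1, 0.05, 0.05))
        assert dist.omega == pytest.approx(0.2, abs=1e-12)


class TestAnalyticRates:
    @pytest.mark.parametrize(
        "probs, m, expected_delta",
        [
            ((0.9, 0.1), 3, 0.028),            # single outlier at 10%
            ((0.9, 0.1), 1, 0.1),              # 1-oo-1 reduces to delta = omega
            ((0.8, 0.1, 0.05, 0.05), 3, 0.0425),
            ((0.8, 0.15, 0.05), 3, 0.068),
        ],
    )
    def test_delta_reference_values(self, probs, m, expected_delta):
        rates = rule_rates(OutcomeDistribution(probs), m)
        assert rates.delta == pytest.approx(expected_delta, abs=1e-12)

    def test_inconclusive_reference_value(self):
        rates = rule_rates(OutcomeDistribution((0.8, 0.1, 0.05, 0.05)), 3)
        assert rates.inconclusive == pytest.approx(0.0615, abs=1e-12)

    def test_rates_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            k = int(rng.integers(1, 6))
            m = int(rng.integers(1, 8))
            rates = rule_rates(random_distribution(rng, k), m)
            total = rates.correct + rates.incorrect + rates.inconclusive
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_outlier_limit(self):
        rates = rule_rates(OutcomeDistribution.single_outlier(0.0), 3)
        assert rates.correct == 1.0
        assert rates.incorrect == 0.0


class TestOracleEquivalence:
    def test_matches_enumeration_on_seeded_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            k = int(rng.integers(1, 6))
            m = int(rng.integers(1, 8))
            dist = random_distribution(rng, k)
            analytic = rule_rates(dist, m)
            exact = enumerate_exact(dist, m)
            assert analytic.correct == pytest.approx(exact.correct, abs=1e-12)
            assert analytic.incorrect == pytest.approx(exact.incorrect, abs=1e-12)
            assert analytic.inconclusive == pytest.approx(
                exact.inconclusive, abs=1e-12
            )

    def test_enumeration_guard(self):
        dist = OutcomeDistribution((0.6, 0.1, 0.1, 0.1, 0.1))
        with pytest.raises(ResourceGuardError):
            enumerate_exact(dist, 11)  # 5^11 > 1e7


class TestDeltaCurves:
    @pytest.mark.parametrize(
        "m, omega, expected",
        [
            (3, 0.2, 0.104),
            (3, 0.0, 0.0),
            (3, 0.1, 0.028),
        ],
    )
    def test_single_outlier_closed_form(self, m, omega, expected):
        assert delta_curve(m, [omega])[0] == pytest.approx(expected, abs=1e-12)

    def test_identity_for_single_subject(self):
        grid = np.linspace(0.0, 0.49, 20)
        np.testing.assert_allclose(delta_curve(1, grid), grid, atol=1e-12)

    @pytest.mark.parametrize("m", [1, 3, 5, 7])
    def test_strictly_increasing_in_omega(self, m):
        grid = np.linspace(0.0, 0.499, 60)
        assert (np.diff(delta_curve(m, grid)) > 0).all()

    def test_domain_capped_below_half(self):
        with pytest.raises(InputDomainError):
            delta_curve(3, [0.5])

    def test_difference_peaks_at_intermediate_omega(self):
        assert delta_difference(0.0) == 0.0
        assert delta_difference(0.1) == pytest.approx(0.1 - 0.028, abs=1e-12)
        peak = delta_difference(0.21)
        assert peak > delta_difference(0.05)
        assert peak > delta_difference(0.45)
        assert delta_difference(0.21) == pytest.approx(
            0.21 - (3 * 0.21**2 - 2 * 0.21**3), abs=1e-12
        )


class TestOmegaThreshold:
    def test_five_percent_target_for_majority_of_three(self):
        omega = omega_threshold(3, 0.05)
        assert delta_curve(3, [omega])[0] == pytest.approx(0.05, abs=1e-10)
        # analytically this coincides with the one-sided p bound for 2-oo-3
        assert omega == pytest.approx(0.13535, abs=5e-6)

    def test_single_subject_is_identity(self):
        assert omega_threshold(1, 0.05) == pytest.approx(0.05, abs=1e-10)

    def test_inverts_known_delta(self):
        assert omega_threshold(3, 0.028) == pytest.approx(0.1, abs=1e-10)

    def test_unachievable_target_rejected(self):
        with pytest.raises(InputDomainError):
            omega_threshold(3, 0.9)

    def test_min_integer_typicality(self):
        assert min_typicality_percent(3, 0.05) == 87
        assert min_typicality_percent(1, 0.05) == 95
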