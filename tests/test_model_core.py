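"""Threshold link, case probability, likelihood and canonicalization."""

import numpy as np
import pytest

from tilor.model import (
    DegenerateParameterError,
    GenotypeMatrix,
    ThresholdLinkParams,
    TILoRParams,
    canonicalize,
    case_probability,
    eval_threshold_link,
    log_likelihood,
    pack_params,
    penalized_objective,
    unpack_params,
)


def make_theta(alpha, beta, g1=None, g2=None):
    g1 = g1 or ThresholdLinkParams(0.0, 0.0, 0.0, 0.0, 0.0)
    g2 = g2 or ThresholdLinkParams(0.0, 0.0, 0.0, 0.0, 0.0)
    return TILoRParams(np.asarray(alpha, float), np.asarray(beta, float), g1, g2)


def random_theta(rng, p):
    alpha = rng.normal(size=p)
    beta = rng.normal(size=p)
    g1 = ThresholdLinkParams(*rng.normal(size=4), rng.normal())
    g2 = ThresholdLinkParams(*rng.normal(size=4), rng.normal())
    return TILoRParams(alpha, beta, g1, g2)


class TestThresholdLink:
    @pytest.mark.parametrize(
        "b, c, u, expected",
        [
            ((0, 0, 0, 0), 0.0, 7.3, 0.0),
            ((1, 2, 3, 4), 0.0, -1.0, -1.0),   # lower regime: 1 + 2*(-1)
            ((1, 2, 3, 4), 0.0, 1.0, 7.0),     # upper regime: 3 + 4*1
            ((1, 2, 3, 4), 0.0, 0.0, 1.0),     # boundary belongs to lower regime
        ],
    )
    def test_regime_evaluation(self, b, c, u, expected):
        link = ThresholdLinkParams(*b, c)
        assert eval_threshold_link(link, u) == pytest.approx(expected, abs=1e-15)

    def test_nonfinite_argument_rejected(self):
        link = ThresholdLinkParams(1, 2, 3, 4, 0)
        with pytest.raises(ValueError):
            eval_threshold_link(link, np.inf)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ThresholdLinkParams(np.nan, 0, 0, 0, 0)

    def test_affine_within_each_regime(self):
        """Second differences vanish on grids strictly inside one regime."""
        link = ThresholdLinkParams(0.7, -1.3, 2.1, 0.4, 0.5)
        for grid in (np.linspace(-10, 0.4, 50), np.linspace(0.6, 10, 50)):
            vals = eval_threshold_link(link, grid)
            assert np.abs(np.diff(vals, 2)).max() < 1e-12


class TestCaseProbability:
    def test_all_zero_coefficients_give_half(self):
        theta = make_theta([1, 0], [0, 1])
        assert case_probability(theta, [2, 1]) == pytest.approx(0.5)

    def test_log3_predictor_gives_three_quarters(self):
        # g1 contributes ln 3 regardless of u (slopes zero), g2 contributes 0
        g1 = ThresholdLinkParams(np.log(3.0), 0, np.log(3.0), 0, 0.0)
        theta = make_theta([1, 0], [0, 1], g1=g1)
        assert case_probability(theta, [0, 2]) == pytest.approx(0.75, abs=1e-12)

    def test_saturation_does_not_underflow_to_zero(self):
        g1 = ThresholdLinkParams(-50.0, 0, -50.0, 0, 0.0)
        theta = make_theta([1, 0], [0, 1], g1=g1)
        prob = case_probability(theta, [1, 1])
        assert 0 < prob < 1e-20

    def test_dimension_mismatch(self):
        theta = make_theta([1, 0], [0, 1])
        with pytest.raises(ValueError):
            case_probability(theta, [1, 1, 1])

    def test_monotone_in_linear_predictor(self):
        # constant-slope links: probability increases with the intercepts
        probs = [
            case_probability(
                make_theta([1, 0], [0, 1], g1=ThresholdLinkParams(v, 0, v, 0, 0.0)),
                [1, 1],
            )
            for v in np.linspace(-3, 3, 13)
        ]
        assert np.all(np.diff(probs) > 0)


class TestLogLikelihood:
    def test_all_zero_theta_counts_ln_half(self):
        rng = np.random.default_rng(0)
        data = GenotypeMatrix(rng.integers(0, 3, (10, 2)), np.array([1, 0] * 5))
        theta = make_theta([1, 0], [0, 1])
        assert log_likelihood(theta, data) == pytest.approx(10 * np.log(0.5), abs=1e-12)

    def test_single_observation_value(self):
        g1 = ThresholdLinkParams(np.log(3.0), 0, np.log(3.0), 0, 0.0)
        theta = make_theta([1, 0], [0, 1], g1=g1)
        data = GenotypeMatrix(np.array([[1, 1]]), np.array([1]))
        assert log_likelihood(theta, data) == pytest.approx(np.log(0.75), abs=1e-12)

    def test_matches_bernoulli_product_oracle(self):
        """Log-likelihood equals the log of the product of per-subject
        Bernoulli likelihoods, computed independently, on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 31))
            p = int(rng.integers(2, 6))
            data = GenotypeMatrix(
                rng.integers(0, 3, (n, p)), rng.integers(0, 2, n)
            )
            theta = random_theta(rng, p)
            product = 1.0
            for i in range(n):
                pi = case_probability(theta, data.genotypes[i])
                product *= pi if data.phenotype[i] == 1 else (1.0 - pi)
            assert log_likelihood(theta, data) == pytest.approx(
                np.log(product), abs=1e-10
            )

    def test_never_positive(self):
        rng = np.random.default_rng(3)
        data = GenotypeMatrix(rng.integers(0, 3, (25, 3)), rng.integers(0, 2, 25))
        for _ in range(10):
            assert log_likelihood(random_theta(rng, 3), data) <= 0


class TestPenalizedObjective:
    def test_unit_norm_indices_give_plain_likelihood(self):
        rng = np.random.default_rng(1)
        data = GenotypeMatrix(rng.integers(0, 3, (12, 2)), rng.integers(0, 2, 12))
        theta = make_theta([0.6, 0.8], [1.0, 0.0])
        assert penalized_objective(theta, data, 1e3) == pytest.approx(
            log_likelihood(theta, data), abs=1e-12
        )

    def test_norm_two_penalty_value(self):
        rng = np.random.default_rng(2)
        data = GenotypeMatrix(rng.integers(0, 3, (12, 2)), rng.integers(0, 2, 12))
        theta = make_theta([1.2, 1.6], [1.0, 0.0])  # ||alpha|| = 2
        expected = log_likelihood(theta, data) - 1000.0 * (2.0 - 1.0) ** 2
        assert penalized_objective(theta, data, 1000.0) == pytest.approx(
            expected, abs=1e-10
        )

    def test_never_exceeds_likelihood(self):
        rng = np.random.default_rng(7)
        data = GenotypeMatrix(rng.integers(0, 3, (20, 4)), rng.integers(0, 2, 20))
        for _ in range(10):
            theta = random_theta(rng, 4)
            assert penalized_objective(theta, data, 500.0) <= log_likelihood(
                theta, data
            ) + 1e-12


class TestCanonicalize:
    def test_canonical_theta_unchanged(self):
        theta = make_theta([0.6, 0.8], [1.0, 0.0],
                           g1=ThresholdLinkParams(1, 2, 3, 4, 0.5))
        out = canonicalize(theta)
        np.testing.assert_allclose(out.alpha, theta.alpha, atol=1e-15)
        np.testing.assert_allclose(out.beta, theta.beta, atol=1e-15)
        assert out.g1.c == pytest.approx(theta.g1.c)

    def test_rescaling_is_compensated(self):
        """Doubling alpha: canonical form has halved threshold, doubled
        slopes, and identical probabilities everywhere."""
        rng = np.random.default_rng(5)
        g1 = ThresholdLinkParams(0.5, -1.0, 2.0, 0.3, 0.8)
        g2 = ThresholdLinkParams(-0.2, 0.7, 1.0, -0.4, 0.1)
        theta = TILoRParams(np.array([1.2, 1.6]), np.array([0.0, 1.0]), g1, g2)
        out = canonicalize(theta)
        np.testing.assert_allclose(out.alpha, [0.6, 0.8], atol=1e-12)
        assert out.g1.c == pytest.approx(0.8 / 2.0)
        assert out.g1.b2 == pytest.approx(-1.0 * 2.0)
        assert out.g1.b4 == pytest.approx(0.3 * 2.0)
        X = rng.integers(0, 3, (100, 2))
        np.testing.assert_allclose(
            case_probability(theta, X), case_probability(out, X), atol=1e-10
        )

    def test_sign_flip_mirrors_link(self):
        # threshold 0.79 is not attainable by any genotype combination of
        # the (0.6, 0.8) loadings, so no subject sits on the regime boundary
        rng = np.random.default_rng(6)
        g1 = ThresholdLinkParams(0.5, -1.0, 2.0, 0.3, 0.79)
        theta = make_theta([-0.6, 0.8], [1.0, 0.0], g1=g1)
        out = canonicalize(theta)
        np.testing.assert_allclose(out.alpha, [0.6, -0.8], atol=1e-12)
        # regimes swapped, slopes negated, threshold sign flipped
        assert out.g1.b1 == pytest.approx(2.0)
        assert out.g1.b2 == pytest.approx(-0.3)
        assert out.g1.b3 == pytest.approx(0.5)
        assert out.g1.b4 == pytest.approx(1.0)
        assert out.g1.c == pytest.approx(-0.79)
        X = rng.integers(0, 3, (100, 2))
        np.testing.assert_allclose(
            case_probability(theta, X), case_probability(out, X), atol=1e-10
        )

    def test_general_invariance_property(self):
        """Arbitrary nonzero rescalings of both indices leave the model's
        probabilities invariant after canonicalization."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = int(rng.integers(2, 6))
            theta = random_theta(rng, p)
            base = canonicalize(theta)
            s1, s2 = rng.choice([-1, 1], 2) * rng.uniform(0.2, 5.0, 2)

            def compensated(link, s):
                # rescaling the index by s rescales slopes/threshold; a
                # negative s additionally reverses the regime order
                if s > 0:
                    return ThresholdLinkParams(
                        link.b1, link.b2 / s, link.b3, link.b4 / s, link.c * s
                    )
                return ThresholdLinkParams(
                    link.b3, link.b4 / s, link.b1, link.b2 / s, link.c * s
                )

            scaled = TILoRParams(
                s1 * base.alpha,
                s2 * base.beta,
                compensated(base.g1, s1),
                compensated(base.g2, s2),
            )
            out = canonicalize(scaled)
            X = rng.integers(0, 3, (100, p))
            np.testing.assert_allclose(
                case_probability(base, X), case_probability(out, X), atol=1e-10
            )
            assert np.linalg.norm(out.alpha) == pytest.approx(1.0, abs=1e-10)
            assert np.linalg.norm(out.beta) == pytest.approx(1.0, abs=1e-10)

    def test_zero_index_rejected(self):
        theta = make_theta([0.0, 0.0], [1.0, 0.0])
        with pytest.raises(DegenerateParameterError):
            canonicalize(theta)


class TestPacking:
    def test_round_trip(self):
        rng = np.random.default_rng(8)
        theta = random_theta(rng, 5)
        again = unpack_params(pack_params(theta), 5)
        np.testing.assert_allclose(pack_params(again), pack_params(theta))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            unpack_params(np.zeros(7), 5)


class TestGenotypeMatrix:
    def test_rejects_out_of_range_codes(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.array([[0, 3]]), np.array([1]))

    def test_rejects_duplicate_snp_ids(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.array([[0, 1]]), np.array([1]), snp_ids=["a", "a"])

    def test_rejects_nonbinary_phenotype(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.array([[0, 1]]), np.array([2]))
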