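import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmobile import (
    ErrorPosterior,
    PriorHyperparameters,
    SnpCounts,
    fit_error_posterior,
    log_beta_binomial,
    posterior_over_n2,
    snp_log_bf,
    transcript_log_bf,
)

from oracles import brute_force_posterior, quadrature_beta_binomial


class TestSnpCounts:
    def test_valid(self):
        c = SnpCounts("s1", "r1", 10, 3)
        assert (c.total_reads, c.distal_reads) == (10, 3)

    @pytest.mark.parametrize("N,n", [(10, 11), (10, -1), (-1, 0)])
    def test_invalid_rejected(self, N, n):
        with pytest.raises(ValueError):
            SnpCounts("s1", "r1", N, n)


class TestFitErrorPosterior:
    def test_single_replicate(self):
        post = fit_error_posterior([SnpCounts("s", "r1", 100, 3)])
        assert (post.alpha, post.beta) == (4.0, 98.0)

    def test_empty_returns_prior_with_warning(self):
        with pytest.warns(UserWarning, match="low information"):
            post = fit_error_posterior([])
        assert (post.alpha, post.beta) == (1.0, 1.0)

    def test_split_equals_pooled_exactly(self):
        split = fit_error_posterior(
            [SnpCounts("s", "r1", 50, 1), SnpCounts("s", "r2", 50, 2)]
        )
        pooled = fit_error_posterior([SnpCounts("s", "r1", 100, 3)])
        assert split.alpha == pooled.alpha == 4.0
        assert split.beta == pooled.beta == 98.0

    def test_replicate_order_irrelevant(self):
        counts = [SnpCounts("s", f"r{i}", 40, i) for i in range(4)]
        forward = fit_error_posterior(counts)
        backward = fit_error_posterior(list(reversed(counts)))
        assert (forward.alpha, forward.beta) == (backward.alpha, backward.beta)

    def test_mixed_snps_rejected(self):
        with pytest.raises(ValueError, match="share one snp_id"):
            fit_error_posterior([SnpCounts("a", "r1", 10, 0), SnpCounts("b", "r1", 10, 0)])

    def test_posterior_mean_formula(self):
        prior = PriorHyperparameters(u1=2.0, u2=3.0)
        post = fit_error_posterior([SnpCounts("s", "r1", 20, 4)], prior)
        assert post.mean == pytest.approx((2 + 4) / (2 + 3 + 20))

    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorHyperparameters(u1=0.0)


class TestLogBetaBinomial:
    @pytest.mark.parametrize("k", [0, 3, 10])
    def test_flat_prior_uniform(self, k):
        assert log_beta_binomial(k, 10, 1, 1) == pytest.approx(math.log(1 / 11))

    def test_empty_trial(self):
        assert log_beta_binomial(0, 0, 4, 98) == pytest.approx(0.0)

    def test_against_quadrature_oracle(self):
        expected = quadrature_beta_binomial(2, 10, 4.0, 98.0)
        assert math.exp(log_beta_binomial(2, 10, 4.0, 98.0)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_frozen_oracle_value(self):
        # quadrature oracle value for (k=2, m=10, Beta(4, 98)), computed once
        assert math.exp(log_beta_binomial(2, 10, 4.0, 98.0)) == pytest.approx(
            0.05409655, abs=1e-6
        )

    @pytest.mark.parametrize("m,a,b", [(0, 1, 1), (7, 0.5, 3.2), (25, 4, 98)])
    def test_normalizes(self, m, a, b):
        k = np.arange(m + 1)
        assert np.exp(log_beta_binomial(k, m, a, b)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            log_beta_binomial(11, 10, 1, 1)
        with pytest.raises(ValueError):
            log_beta_binomial(-1, 10, 1, 1)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            log_beta_binomial(1, 2, 0.0, 1.0)


def _flat(snp="s"):
    return ErrorPosterior(alpha=1.0, beta=1.0, snp_id=snp)


class TestPosteriorOverN2:
    def test_impossible_count_excluded(self):
        post = posterior_over_n2(SnpCounts("s", "r1", 1, 0), _flat())
        assert post.probabilities[0] == pytest.approx(1.0)
        assert post.probabilities[1] == 0.0

    def test_frozen_two_read_example(self):
        # confirmed by the brute-force enumeration oracle below
        post = posterior_over_n2(SnpCounts("s", "r1", 2, 1), _flat())
        np.testing.assert_allclose(post.probabilities, [0.4, 0.6, 0.0], atol=1e-12)
        assert post.expected_n2 == pytest.approx(0.6)
        assert post.ratio_r2 == pytest.approx(0.3)

    def test_two_read_example_matches_oracle(self):
        oracle = brute_force_posterior(2, 1, 1.0, 1.0)
        post = posterior_over_n2(SnpCounts("s", "r1", 2, 1), _flat())
        np.testing.assert_allclose(post.probabilities, oracle, atol=1e-6)

    def test_zero_reads_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="zero reads"):
            post = posterior_over_n2(SnpCounts("s", "r1", 0, 0), _flat())
        assert post.probabilities.tolist() == [1.0]
        assert post.expected_n2 == 0.0

    def test_mismatched_snp_rejected(self):
        with pytest.raises(ValueError, match="snp"):
            posterior_over_n2(SnpCounts("s1", "r1", 5, 1), _flat("s2"))

    def test_mismatched_tissue_rejected(self):
        loc = ErrorPosterior(2.0, 9.0, tissue="scion", genotype="A")
        dist = ErrorPosterior(2.0, 9.0, tissue="stock", genotype="B")
        with pytest.raises(ValueError, match="tissue"):
            posterior_over_n2(SnpCounts("s", "r1", 5, 1), loc, dist)

    def test_same_genotype_pairing_rejected(self):
        loc = ErrorPosterior(2.0, 9.0, genotype="A")
        dist = ErrorPosterior(2.0, 9.0, genotype="A")
        with pytest.raises(ValueError, match="genotype"):
            posterior_over_n2(SnpCounts("s", "r1", 5, 1), loc, dist)

    @pytest.mark.parametrize("two_rate", [False, True])
    @pytest.mark.parametrize("N,n", [(1, 1), (4, 2), (6, 6), (6, 0)])
    def test_oracle_equivalence_small(self, N, n, two_rate):
        loc = ErrorPosterior(2.0, 5.0)
        dist = ErrorPosterior(1.0, 3.0) if two_rate else None
        post = posterior_over_n2(SnpCounts("s", "r1", N, n), loc, dist)
        oracle = brute_force_posterior(
            N, n, 2.0, 5.0, 1.0 if two_rate else None, 3.0 if two_rate else None
        )
        np.testing.assert_allclose(post.probabilities, oracle, atol=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(
        N=st.integers(min_value=1, max_value=40),
        frac=st.floats(min_value=0.0, max_value=1.0),
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=0.1, max_value=50.0),
        two_rate=st.booleans(),
    )
    def test_normalization_property(self, N, frac, a, b, two_rate):
        n = int(round(frac * N))
        prior = PriorHyperparameters(u1=min(a, b), u2=min(a, b))
        dist = ErrorPosterior(b, a, prior=prior) if two_rate else None
        post = posterior_over_n2(
            SnpCounts("s", "r1", N, n), ErrorPosterior(a, b, prior=prior), dist
        )
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (post.probabilities >= 0).all()
        assert post.probabilities[0] > 0
        assert post.expected_n2 == pytest.approx(
            float(np.dot(np.arange(N + 1), post.probabilities))
        )
        assert 0.0 <= post.ratio_r2 <= 1.0


class TestSnpLogBf:
    def test_frozen_ratio(self):
        post = posterior_over_n2(SnpCounts("s", "r1", 2, 1), _flat())
        assert snp_log_bf(post) == pytest.approx(math.log10(1.5))

    def test_zero_reads_no_evidence(self):
        with pytest.warns(UserWarning):
            post = posterior_over_n2(SnpCounts("s", "r1", 0, 0), _flat())
        assert snp_log_bf(post) == 0.0

    def test_error_dominated_count_is_negative(self):
        # n well below the expected error count: evidence against mobility
        loc = ErrorPosterior(101.0, 9901.0)
        post = posterior_over_n2(SnpCounts("s", "r1", 1000, 5), loc)
        assert snp_log_bf(post) < 0

    def test_monotone_in_n_above_expected_errors(self):
        loc = ErrorPosterior(3.0, 200.0)
        N = 150
        start = math.ceil(loc.mean * N)
        values = [
            snp_log_bf(posterior_over_n2(SnpCounts("s", "r1", N, n), loc))
            for n in range(start, N + 1)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_full_distal_exceeds_zero_distal(self):
        loc = ErrorPosterior(3.0, 200.0)
        N = 80
        at_zero = snp_log_bf(posterior_over_n2(SnpCounts("s", "r1", N, 0), loc))
        at_full = snp_log_bf(posterior_over_n2(SnpCounts("s", "r1", N, N), loc))
        assert at_full > at_zero


class TestTranscriptLogBf:
    def test_single_entry_below_threshold(self):
        ev = transcript_log_bf({("s1", "r1"): 0.5})
        assert ev.total_log_bf == pytest.approx(0.5)
        assert ev.label == "non-mobile"

    def test_additivity_crosses_threshold(self):
        ev = transcript_log_bf({("s1", "r1"): 0.5, ("s2", "r1"): 0.7})
        assert ev.total_log_bf == pytest.approx(1.2)
        assert ev.label == "mobile"

    def test_boundary_is_mobile(self):
        assert transcript_log_bf({("s1", "r1"): 1.0}).label == "mobile"

    def test_deviant_snp_outvoted(self):
        ev = transcript_log_bf({("s1", "r1"): 1.5, ("s2", "r1"): -2.0})
        assert ev.total_log_bf == pytest.approx(-0.5)
        assert ev.label == "non-mobile"

    def test_confident_non_mobile_flag(self):
        ev = transcript_log_bf({("s1", "r1"): -1.2})
        assert ev.confident_non_mobile
        assert not transcript_log_bf({("s1", "r1"): -0.5}).confident_non_mobile

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no SNP contributions"):
            transcript_log_bf({})

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=1, max_size=8))
    def test_total_is_sum(self, values):
        contributions = {(f"s{i}", "r1"): v for i, v in enumerate(values)}
        ev = transcript_log_bf(contributions)
        assert ev.total_log_bf == pytest.approx(sum(values), abs=1e-9)
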