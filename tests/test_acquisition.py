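"""Batch acquisition: posterior updates, constant-liar, diversity."""

import numpy as np
import pytest

from folde import (AcquisitionConfig, PredictionEnsemble, constant_liar_select,
                   covariance_posterior, diversity_report, mean_posterior,
                   parse_mutation_string, random_select, top_n_select)
from folde.synthetic import clustered_prediction_ensemble

from conftest import random_psd


def conditional_moments_oracle(mean, cov, i, value):
    """Gaussian conditioning via an independent block-inverse route.

    Condition the joint N(mean, cov) on coordinate i taking ``value``;
    returns (mean', cov') over the remaining coordinates.
    """
    n = len(mean)
    rest = [j for j in range(n) if j != i]
    S_rr = cov[np.ix_(rest, rest)]
    S_ri = cov[np.ix_(rest, [i])]
    S_ii = cov[i, i]
    mu = mean[rest] + (S_ri / S_ii).ravel() * (value - mean[i])
    Sig = S_rr - S_ri @ S_ri.T / S_ii
    return mu, Sig


class TestPosteriorUpdates:
    def test_identity_covariance_unchanged(self):
        cov = np.eye(4)
        out = covariance_posterior(cov, 2)
        np.testing.assert_allclose(out, np.eye(3), atol=1e-12)

    def test_perfect_correlation_collapses(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = covariance_posterior(cov, 0)
        np.testing.assert_allclose(out, [[0.0]], atol=1e-12)

    def test_lie_equal_to_prediction_is_noop(self):
        rng = np.random.default_rng(0)
        cov = random_psd(rng, 5)
        y = rng.normal(size=5)
        out = mean_posterior(y, cov, 1, y_lie=y[1])
        np.testing.assert_allclose(out, np.delete(y, 1), atol=1e-12)

    def test_uncorrelated_pick_leaves_mean(self):
        cov = np.diag([1.0, 2.0, 3.0])
        y = np.array([0.5, -0.5, 1.5])
        out = mean_posterior(y, cov, 0, y_lie=-10.0)
        np.testing.assert_allclose(out, y[1:], atol=1e-12)

    def test_hand_arithmetic_two_correlated_candidates(self):
        # unit variances, c1/c2 fully correlated, pessimistic lie on c1
        cov = np.array([[1.0, 1.0, 0.0],
                        [1.0, 1.0, 0.0],
                        [0.0, 0.0, 1.0]])
        y = np.array([1.0, 0.9, 0.0])
        out = mean_posterior(y, cov, 0, y_lie=0.0)
        assert out[0] == pytest.approx(-0.1)   # c2 dragged below c3
        assert out[1] == pytest.approx(0.0)
        assert out[0] < out[1]

    def test_matches_gaussian_conditioning_oracle(self):
        """Rank-one updates equal full block conditioning on random PSD
        matrices, entrywise to 1e-10."""
        rng = np.random.default_rng(1)
        for trial in range(100):
            n = int(rng.integers(2, 9))
            cov = random_psd(rng, n)
            y = rng.normal(size=n)
            i = int(rng.integers(n))
            lie = float(rng.normal())
            mu_o, Sig_o = conditional_moments_oracle(y, cov, i, lie)
            np.testing.assert_allclose(mean_posterior(y, cov, i, lie), mu_o,
                                       atol=1e-10)
            np.testing.assert_allclose(covariance_posterior(cov, i), Sig_o,
                                       atol=1e-10)

    def test_zero_variance_errors(self):
        cov = np.zeros((3, 3))
        with pytest.raises(ValueError, match="jitter"):
            covariance_posterior(cov, 0)

    def test_posterior_stays_symmetric_psd(self):
        rng = np.random.default_rng(2)
        cov = random_psd(rng, 8)
        for _ in range(5):
            i = int(rng.integers(cov.shape[0]))
            cov = covariance_posterior(cov, i)
            cov[np.diag_indices_from(cov)] += 1e-6  # jitter as in selection
            np.testing.assert_allclose(cov, cov.T, atol=1e-8)
            assert np.linalg.eigvalsh(cov).min() > -1e-8


def _random_ensemble(rng, n_candidates=50, n_members=5):
    raw = rng.normal(size=(n_members, n_candidates))
    ids = [f"c{i}" for i in range(n_candidates)]
    return PredictionEnsemble.from_member_scores(ids, raw)


class TestTopN:
    def test_selects_highest_consensus(self):
        pe = PredictionEnsemble.from_member_scores(
            ["a", "b", "c"], np.array([[3.0, 1.0, 2.0]] * 2))
        batch = top_n_select(pe, 2)
        assert batch.selected_ids == ("a", "c")

    def test_batch_larger_than_pool(self):
        pe = PredictionEnsemble.from_member_scores(
            ["a", "b"], np.array([[1.0, 2.0]] * 2))
        assert len(top_n_select(pe, 10)) == 2


class TestConstantLiar:
    def test_large_alpha_limit_recovers_top_n(self):
        """As α grows the lie's 1/α-scaled impact vanishes: selection is
        exactly top-N in the limit, and already within a single boundary
        swap of it at α = 100."""
        rng = np.random.default_rng(3)
        exact = 0
        swapped_at_100 = []
        for _ in range(100):
            pe = _random_ensemble(rng)
            top = set(top_n_select(pe, 16).selected_ids)
            cl_limit = set(constant_liar_select(
                pe, AcquisitionConfig(batch_size=16, alpha=1e5)).selected_ids)
            exact += top == cl_limit
            cl_100 = set(constant_liar_select(
                pe, AcquisitionConfig(batch_size=16, alpha=100.0)).selected_ids)
            swapped_at_100.append(len(top ^ cl_100) // 2)
        assert exact == 100
        assert np.mean(swapped_at_100) <= 1.0

    def test_diagonal_covariance_equals_top_n_any_alpha(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=20)
        ids = [f"c{i}" for i in range(20)]
        pe = PredictionEnsemble(candidate_ids=ids, member_scores=np.zeros((5, 20)),
                                consensus=y, covariance=np.diag(rng.uniform(0.5, 2.0, 20)))
        top = top_n_select(pe, 8).selected_ids
        for alpha in (0.1, 1.0, 10.0):
            cl = constant_liar_select(
                pe, AcquisitionConfig(batch_size=8, alpha=alpha)).selected_ids
            assert cl == top

    def test_two_clusters_alternate_at_small_alpha(self):
        pe, muts = clustered_prediction_ensemble(n_per_cluster=16, seed=5)
        cl = constant_liar_select(pe, AcquisitionConfig(batch_size=8, alpha=0.5))
        loci = [muts[i][0].position for i in cl.selected_ids]
        assert set(loci) == {1, 2}       # both clusters visited
        top = top_n_select(pe, 8).selected_ids
        top_loci = {muts[i][0].position for i in top}
        assert top_loci == {1}           # exploitation stays in cluster 1

    def test_zero_covariance_falls_back_to_top_n(self):
        pe = PredictionEnsemble.from_member_scores(
            ["a", "b", "c"], np.array([[3.0, 1.0, 2.0]] * 5))
        batch = constant_liar_select(pe, AcquisitionConfig(batch_size=2))
        assert batch.selected_ids == ("a", "c")

    def test_trace_records_pick_time_means(self):
        rng = np.random.default_rng(6)
        pe = _random_ensemble(rng, 12)
        batch = constant_liar_select(pe, AcquisitionConfig(batch_size=5, alpha=1.0))
        assert len(batch.selection_trace) == 5
        assert batch.selection_trace[0] == pytest.approx(pe.consensus.max())

    def test_alpha_diversity_direction(self):
        """Mean unique loci per batch is non-increasing in α on two-cluster
        ensembles (exploration fades as the lie weakens)."""
        means = {}
        for alpha in (1.0, 6.0, 100.0):
            counts = []
            for seed in range(20):
                pe, muts = clustered_prediction_ensemble(n_per_cluster=18,
                                                         seed=seed)
                batch = constant_liar_select(
                    pe, AcquisitionConfig(batch_size=16, alpha=alpha))
                counts.append(len({muts[i][0].position
                                   for i in batch.selected_ids}))
            means[alpha] = np.mean(counts)
        assert means[1.0] >= means[6.0] >= means[100.0]
        assert means[1.0] > means[100.0]


class TestRandomSelect:
    def test_seeded_and_distinct(self):
        pool = [f"c{i}" for i in range(100)]
        b1 = random_select(pool, 16, seed=7)
        b2 = random_select(pool, 16, seed=7)
        assert b1.selected_ids == b2.selected_ids
        assert len(set(b1.selected_ids)) == 16

    def test_uniform_frequencies(self):
        pool = [f"c{i}" for i in range(100)]
        rng = np.random.default_rng(8)
        counts = {i: 0 for i in pool}
        n_draws = 2000
        for _ in range(n_draws):
            for i in random_select(pool, 16, rng).selected_ids:
                counts[i] += 1
        p = 16 / 100
        se = np.sqrt(p * (1 - p) * n_draws)
        expected = p * n_draws
        assert all(abs(c - expected) < 4 * se for c in counts.values())


class TestDiversityReport:
    def test_distinct_loci(self):
        muts = [parse_mutation_string(f"A{i}C") for i in range(1, 17)]
        rep = diversity_report(muts, [])
        assert rep.unique_loci == 16 and rep.new_loci == 16

    def test_single_locus(self):
        muts = [[m] for m in
                (parse_mutation_string(f"A1{aa}")[0] for aa in "CDEFG")]
        rep = diversity_report(muts, [])
        assert rep.unique_loci == 1

    def test_no_new_loci_when_history_covers(self):
        first = [parse_mutation_string(f"A{i}C") for i in range(1, 9)]
        second = [parse_mutation_string(f"A{i}D") for i in range(1, 5)]
        rep = diversity_report(second, first)
        assert rep.new_loci == 0 and rep.unique_loci == 4
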