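"""Directed pairs, the BFS-constrained split, training, and ensembles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from folde import (DirectedPair, MLPRanker, PredictionEnsemble, TrainConfig,
                   build_directed_pairs, build_table, fit_ensemble,
                   make_oracle, predict_ensemble, split_pairs,
                   train_member_activity, warm_start_member)
from folde.synthetic import SyntheticOracleConfig


class TestBuildDirectedPairs:
    def test_all_distinct_targets(self):
        pairs = build_directed_pairs({"a": 1.0, "b": 2.0, "c": 3.0})
        assert len(pairs) == 3
        assert DirectedPair("c", "a") in pairs
        assert DirectedPair("b", "a") in pairs
        assert DirectedPair("c", "b") in pairs

    def test_ties_produce_no_pair(self):
        pairs = build_directed_pairs({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0})
        assert len(pairs) == 5  # C(4,2)=6 minus the (b,c) tie

    def test_single_record(self):
        assert build_directed_pairs({"a": 1.0}) == []

    def test_winner_first_orientation(self):
        for p in build_directed_pairs({"lo": 0.0, "hi": 1.0}):
            assert p.winner_id == "hi"


def _train_reaches(train_pairs, a, b):
    """Independent reachability oracle via networkx."""
    import networkx as nx
    g = nx.DiGraph()
    g.add_edges_from((p.winner_id, p.loser_id) for p in train_pairs)
    return a in g and b in g and nx.has_path(g, a, b)


class TestSplitPairs:
    def test_transitive_pair_excluded_from_validation(self):
        # train holding (A,B) and (B,C) makes (A,C) ineligible
        pairs = [DirectedPair("A", "B"), DirectedPair("B", "C"),
                 DirectedPair("A", "C"), DirectedPair("D", "E"),
                 DirectedPair("F", "G")]
        for seed in range(20):
            split = split_pairs(pairs, val_fraction=0.2, seed=seed)
            if DirectedPair("A", "C") in split.val_pairs:
                assert DirectedPair("A", "B") not in split.train_pairs or \
                    DirectedPair("B", "C") not in split.train_pairs

    def test_quota_targeting(self):
        # star digraph: one winner beats 5 others; all pairs independent
        pairs = [DirectedPair("W", x) for x in "ABCDE"] + \
            [DirectedPair("A", "Z"), DirectedPair("B", "Y"),
             DirectedPair("C", "X"), DirectedPair("D", "V"),
             DirectedPair("E", "U")]
        split = split_pairs(pairs, val_fraction=0.2, seed=0)
        assert len(split.val_pairs) == 2
        assert len(split.train_pairs) + len(split.val_pairs) == len(pairs)

    def test_no_leakage_on_random_digraphs(self):
        """Over many random tournaments, no validation pair is reachable
        through the train digraph (checked with an independent oracle)."""
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(5, 15))
            targets = {f"r{i}": float(rng.normal()) for i in range(n)}
            # random sparse subset of all comparable pairs
            universe = build_directed_pairs(targets)
            take = rng.random(len(universe)) < 0.5
            pairs = [p for p, t in zip(universe, take) if t]
            if len(pairs) < 5:
                continue
            split = split_pairs(pairs, seed=trial)
            for p in split.val_pairs:
                assert not _train_reaches(split.train_pairs, p.winner_id,
                                          p.loser_id)

    def test_deterministic(self):
        targets = {f"r{i}": float(i) for i in range(8)}
        pairs = build_directed_pairs(targets)
        s1 = split_pairs(pairs, seed=5)
        s2 = split_pairs(pairs, seed=5)
        assert s1.val_pairs == s2.val_pairs


@pytest.fixture(scope="module")
def trained_fixture():
    """Small noiseless landscape with embeddings and naturalness table."""
    cfg = SyntheticOracleConfig(L=16, dim=24, naturalness_rho=0.9,
                                signal_fraction=1.0, noise_sd=0.0, seed=30)
    land, oracle = make_oracle(cfg)
    ids = land.single_mutant_ids()
    emb = dict(zip(ids, oracle.embed_many([land.sequence(i) for i in ids])))
    table = build_table(oracle.logprobs(land.wild_type))
    return land, emb, table, cfg


class TestWarmStart:
    def test_member_learns_naturalness_ranking(self, trained_fixture):
        land, emb, table, cfg = trained_fixture
        tc = TrainConfig(input_dim=cfg.dim)
        member = MLPRanker(cfg.dim, seed=0)
        warm_start_member(member, table.entries, emb, tc, seed=1)
        ids = sorted(table.entries)
        X = np.stack([emb[i] for i in ids])
        rho = spearmanr(member.predict(X),
                        [table.entries[i] for i in ids]).statistic
        assert rho > 0.9

    def test_different_seeds_differ(self, trained_fixture):
        land, emb, table, cfg = trained_fixture
        tc = TrainConfig(input_dim=cfg.dim)
        ids = sorted(table.entries)
        X = np.stack([emb[i] for i in ids])
        preds = []
        for k in (0, 1):
            m = MLPRanker(cfg.dim, seed=k)
            warm_start_member(m, table.entries, emb, tc, seed=100 + k)
            preds.append(m.predict(X))
        assert not np.allclose(preds[0], preds[1])

    def test_empty_table_errors(self, trained_fixture):
        _, emb, _, cfg = trained_fixture
        with pytest.raises(ValueError):
            warm_start_member(MLPRanker(cfg.dim, seed=0), {}, emb,
                              TrainConfig(input_dim=cfg.dim))


class TestActivityTraining:
    def test_recovery_on_noiseless_measurements(self, trained_fixture):
        """32 noiseless measurements with informative embeddings rank the
        held-out singles at Spearman >= 0.8 (averaged over 3 seeds)."""
        land, emb, table, cfg = trained_fixture
        tc = TrainConfig(input_dim=cfg.dim)
        ids = land.single_mutant_ids()
        rhos = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            tr = [ids[i] for i in rng.choice(len(ids), 32, replace=False)]
            te = [i for i in ids if i not in set(tr)]
            member = MLPRanker(cfg.dim, seed=seed)
            train_member_activity(member, {i: land.activity(i) for i in tr},
                                  emb, tc, seed=50 + seed)
            X = np.stack([emb[i] for i in te])
            rhos.append(spearmanr(member.predict(X),
                                  land.activities(te)).statistic)
        assert np.mean(rhos) >= 0.8

    def test_two_records_degenerate_path(self, trained_fixture):
        land, emb, _, cfg = trained_fixture
        ids = land.single_mutant_ids()[:2]
        member = MLPRanker(cfg.dim, seed=0)
        hist = train_member_activity(
            member, {ids[0]: 0.0, ids[1]: 1.0}, emb,
            TrainConfig(input_dim=cfg.dim), seed=0)
        assert len(hist) > 0  # trained without validation

    def test_tied_activities_error(self, trained_fixture):
        land, emb, _, cfg = trained_fixture
        ids = land.single_mutant_ids()[:3]
        with pytest.raises(ValueError, match="tied"):
            train_member_activity(MLPRanker(cfg.dim, seed=0),
                                  {i: 1.0 for i in ids}, emb,
                                  TrainConfig(input_dim=cfg.dim))

    def test_monotone_target_transform_leaves_pairs_unchanged(self):
        """Targets enter only through their ordering."""
        t = {"a": 0.1, "b": 2.0, "c": -1.0, "d": 0.5}
        t2 = {k: np.exp(3 * v) for k, v in t.items()}  # strictly monotone
        assert build_directed_pairs(t) == build_directed_pairs(t2)


class TestPredictionEnsemble:
    def test_identical_members_zero_covariance(self):
        raw = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        pe = PredictionEnsemble.from_member_scores(["a", "b", "c"], raw)
        np.testing.assert_allclose(pe.covariance, 0.0, atol=1e-12)
        np.testing.assert_allclose(pe.consensus, [-1.0, 0.0, 1.0])

    def test_shapes_and_rank(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(5, 40))
        pe = PredictionEnsemble.from_member_scores(
            [f"c{i}" for i in range(40)], raw)
        assert pe.member_scores.shape == (5, 40)
        assert pe.covariance.shape == (40, 40)
        assert np.linalg.matrix_rank(pe.covariance, tol=1e-10) <= 4
        np.testing.assert_allclose(pe.member_scores.mean(axis=1), 0.0,
                                   atol=1e-12)

    def test_covariance_equals_brute_force(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(5, 12))
        pe = PredictionEnsemble.from_member_scores(
            [f"c{i}" for i in range(12)], raw)
        demeaned = raw - raw.mean(axis=1, keepdims=True)
        dev = demeaned - demeaned.mean(axis=0)
        brute = sum(np.outer(r, r) for r in dev) / 4
        np.testing.assert_allclose(pe.covariance, brute, atol=1e-12)
        # diagonal equals the per-candidate across-member variance
        np.testing.assert_allclose(np.diag(pe.covariance),
                                   demeaned.var(axis=0, ddof=1), atol=1e-12)

    def test_ensemble_prediction_pipeline(self, trained_fixture):
        land, emb, table, cfg = trained_fixture
        tc = TrainConfig(input_dim=cfg.dim)
        ids = land.single_mutant_ids()[:30]
        acts = {i: land.activity(i) for i in ids[:10]}
        ens = fit_ensemble(acts, emb, tc, base_seed=3)
        pe = predict_ensemble(ens, ids, emb)
        assert len(pe) == 30
        assert pe.member_scores.shape == (5, 30)
        # symmetric PSD within tolerance
        np.testing.assert_allclose(pe.covariance, pe.covariance.T, atol=1e-10)
        w = np.linalg.eigvalsh(pe.covariance)
        assert w.min() > -1e-8
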