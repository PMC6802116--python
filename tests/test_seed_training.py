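import numpy as np
import pytest

from decompart.seed_training import (
    ConsensusMatrix,
    InnerNMFDetails,
    cluster_consensus_to_seed,
    exclusive_weight_scores,
    final_seeded_nmf,
    inner_nmf,
    rank_features_by_exclusive_weight,
    subsample_columns,
)
from decompart.types import FilteredMatrix, TrainingConfig, ValidationError


def _filtered(vals, prefix="g"):
    vals = np.asarray(vals, float)
    return FilteredMatrix(
        vals,
        [f"{prefix}{i}" for i in range(vals.shape[0])],
        [f"s{j}" for j in range(vals.shape[1])],
    )


class TestSubsample:
    def test_eighty_percent_of_ten(self, rng):
        A = _filtered(np.arange(30.0).reshape(3, 10))
        out = subsample_columns(A, 0.8, rng)
        assert out.n_samples == 8
        assert len(set(out.sample_ids)) == 8

    def test_full_fraction_is_identity(self, rng):
        A = _filtered(np.arange(12.0).reshape(3, 4))
        out = subsample_columns(A, 1.0, rng)
        assert out.sample_ids == A.sample_ids
        np.testing.assert_array_equal(out.values, A.values)

    def test_deterministic_given_rng_state(self):
        A = _filtered(np.arange(40.0).reshape(4, 10))
        a = subsample_columns(A, 0.5, np.random.default_rng(7))
        b = subsample_columns(A, 0.5, np.random.default_rng(7))
        assert a.sample_ids == b.sample_ids


class TestInnerNMF:
    def test_exact_rank_one(self, rng):
        w = rng.random(20) + 0.1
        h = rng.random(8) + 0.1
        A = _filtered(np.outer(w, h))
        cfg = TrainingConfig(K_tilde=1, R=1)
        W, H = inner_nmf(A, 1, cfg, rng)
        resid = np.linalg.norm(A.values - W @ H) / np.linalg.norm(A.values)
        assert resid <= 1e-8

    def test_refinement_and_selection_contracts(self, rng):
        A = _filtered(rng.random((30, 12)))
        cfg = TrainingConfig(K_tilde=3, R=1)
        det = InnerNMFDetails()
        inner_nmf(A, 3, cfg, rng, details=det)
        # the selected start has the smallest residual of all candidates
        assert det.candidate_objectives[det.selected] <= det.candidate_objectives.min() + 1e-12
        # ALS refinement never ends worse than its starting candidate
        assert det.refined_objective <= det.candidate_objectives[det.selected] + 1e-12

    def test_multiplicative_updates_monotone(self, rng):
        A = _filtered(rng.random((40, 15)))
        cfg = TrainingConfig(K_tilde=4, R=1, n_inits=6)
        det = InnerNMFDetails()
        inner_nmf(A, 4, cfg, rng, details=det)
        steps = det.step_objectives  # (n_inits, mult_steps)
        assert steps.shape == (6, 10)
        diffs = np.diff(steps, axis=1)
        assert np.all(diffs <= steps[:, :-1] * 1e-12 + 1e-9)

    def test_outputs_nonnegative(self, rng):
        A = _filtered(rng.random((25, 10)))
        W, H = inner_nmf(A, 3, TrainingConfig(K_tilde=3, R=1), rng)
        assert np.all(W >= 0) and np.all(H >= 0)


class TestExclusiveWeightRanking:
    def test_toy_scores(self):
        W = np.array([[5.0, 1.0], [2.0, 3.0]])
        s = exclusive_weight_scores(W, 0)
        np.testing.assert_allclose(s, [4.0, -1.0])
        assert list(rank_features_by_exclusive_weight(W, 0)) == [0, 1]

    def test_identical_columns_keep_input_order(self):
        W = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        assert list(rank_features_by_exclusive_weight(W, 1)) == [0, 1, 2]

    def test_matches_brute_force_sort(self, rng):
        W = rng.random((20, 3))
        for i in range(3):
            scores = np.array(
                [W[g, i] - max(W[g, j] for j in range(3) if j != i) for g in range(20)]
            )
            expected = sorted(range(20), key=lambda g: (-scores[g], g))
            assert list(rank_features_by_exclusive_weight(W, i)) == expected

    def test_single_column_ranks_by_weight(self):
        W = np.array([[1.0], [3.0], [2.0]])
        assert list(rank_features_by_exclusive_weight(W, 0)) == [1, 2, 0]


class TestConsensus:
    def test_single_pair(self):
        C = ConsensusMatrix()
        C.update([["a", "b"]])
        assert C.genes == ["a", "b"]
        np.testing.assert_array_equal(C.counts, [[1, 1], [1, 1]])

    def test_duplicate_top_gene_double_counts_diagonal(self):
        C = ConsensusMatrix()
        C.update([["a", "b"], ["a", "c"]])  # one repetition, two factors
        i = C.genes.index("a")
        assert C.counts[i, i] == 2

    def test_linearity_over_repetitions(self):
        C = ConsensusMatrix()
        for _ in range(5):
            C.update([["a", "b", "c"]])
        assert C.counts[0, 1] == 5 and C.counts[0, 0] == 5

    def test_symmetry_and_bounds(self, rng):
        C = ConsensusMatrix()
        pool = [f"g{i}" for i in range(12)]
        for _ in range(30):
            sets = [list(rng.choice(pool, size=4, replace=False)) for _ in range(2)]
            C.update(sets)
        np.testing.assert_array_equal(C.counts, C.counts.T)
        d = np.diag(C.counts)
        off = C.counts - np.diag(d)
        assert np.all(off <= np.minimum.outer(d, d) + np.diag(d))


class TestConsensusClustering:
    def test_two_disjoint_blocks(self):
        C = ConsensusMatrix()
        for _ in range(10):
            C.update([["a", "b", "c"], ["x", "y"]])
        cfg = TrainingConfig(K_tilde=2)
        seed, genes = cluster_consensus_to_seed(C, 2, cfg)
        assert seed.shape == (5, 2)
        assert np.all(np.isin(seed, [1.0, 0.01]))
        assert np.all((seed == 1.0).sum(axis=1) == 1)  # one high entry per row
        labels = seed.argmax(axis=1)
        by = {g: l for g, l in zip(genes, labels)}
        assert by["a"] == by["b"] == by["c"]
        assert by["x"] == by["y"] != by["a"]

    def test_single_cluster(self):
        C = ConsensusMatrix()
        C.update([["a", "b", "c"]])
        seed, _ = cluster_consensus_to_seed(C, 1, TrainingConfig(K_tilde=1))
        assert np.all(seed == 1.0)

    def test_three_blocks_recovered(self):
        # block-diagonal consensus: clusters must equal the blocks, which
        # an exhaustive scoring of partitions would also select
        C = ConsensusMatrix()
        blocks = [["a1", "a2", "a3"], ["b1", "b2", "b3", "b4"], ["c1", "c2"]]
        for _ in range(20):
            C.update(blocks)
        seed, genes = cluster_consensus_to_seed(C, 3, TrainingConfig(K_tilde=3))
        labels = seed.argmax(axis=1)
        by = {g: l for g, l in zip(genes, labels)}
        for block in blocks:
            assert len({by[g] for g in block}) == 1
        assert len({by[b[0]] for b in blocks}) == 3

    def test_too_few_genes_error(self):
        C = ConsensusMatrix()
        C.update([["a", "b"]])
        with pytest.raises(ValidationError):
            cluster_consensus_to_seed(C, 3, TrainingConfig(K_tilde=3))


class TestFinalSeededNMF:
    def _truth(self, rng, F=60, M=20, K=3, n_markers=10):
        W = np.full((F, K), 0.05)
        for k in range(K):
            W[k * n_markers:(k + 1) * n_markers, k] = 5.0
        H = rng.dirichlet(np.ones(K), size=M).T
        return W, H

    def test_recovers_noiseless_truth_from_true_seed(self, rng):
        W_true, H_true = self._truth(rng)
        A = _filtered(W_true @ H_true)
        cfg = TrainingConfig(K_tilde=3)
        seed = np.where(W_true[:30] > 1, 1.0, 0.01)  # marker blocks as seed
        genes = A.feature_ids[:30]
        res = final_seeded_nmf(A, seed, genes, cfg)
        # Hungarian column matching via correlation
        import scipy.optimize

        corr = np.corrcoef(res.W_prime.T, W_true.T)[:3, 3:]
        r, c = scipy.optimize.linear_sum_assignment(-corr)
        assert np.all(corr[r, c] > 0.99)

    def test_deterministic(self, rng):
        W_true, H_true = self._truth(rng)
        A = _filtered(W_true @ H_true + 0.01)
        cfg = TrainingConfig(K_tilde=3)
        seed = np.where(W_true[:30] > 1, 1.0, 0.01)
        genes = A.feature_ids[:30]
        a = final_seeded_nmf(A, seed, genes, cfg)
        b = final_seeded_nmf(A, seed, genes, cfg)
        np.testing.assert_array_equal(a.W_prime, b.W_prime)

    def test_descent_from_seed(self, rng):
        import scipy.optimize

        W_true, H_true = self._truth(rng)
        A = _filtered(W_true @ H_true + rng.random((60, 20)) * 0.1)
        cfg = TrainingConfig(K_tilde=3)
        seed = np.where(W_true[:30] > 1, 1.0, 0.01)
        genes = A.feature_ids[:30]
        res = final_seeded_nmf(A, seed, genes, cfg)
        W0 = np.full((60, 3), 0.01)
        W0[:30] = seed
        H0 = np.column_stack(
            [scipy.optimize.nnls(W0, A.values[:, j])[0] for j in range(20)]
        )
        baseline = np.linalg.norm(A.values - W0 @ H0, "fro")
        assert res.objective <= baseline + 1e-12

    def test_unknown_seed_gene_error(self, rng):
        A = _filtered(rng.random((10, 5)))
        with pytest.raises(ValidationError, match="absent"):
            final_seeded_nmf(
                A, np.ones((2, 2)), ["nope1", "nope2"], TrainingConfig(K_tilde=2)
            )
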