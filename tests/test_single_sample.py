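import numpy as np
import pytest

from decompart.single_sample import (
    basal_classical_metrics,
    estimate_weights,
    normalize_weights,
    tenfold_cv,
)
from decompart.types import (
    Compartment,
    CompartmentSet,
    ExpressionMatrix,
    ValidationError,
    WeightEstimate,
)


def _compset(W, feature_ids, H=None, M=4):
    K = W.shape[1]
    comps = [Compartment(f"5.{k + 1}", "major", 5, 0.9) for k in range(K)]
    if H is None:
        H = np.zeros((K, M))
    return CompartmentSet(
        compartments=comps,
        W_final=np.asarray(W, float),
        H_final=H,
        feature_ids=list(feature_ids),
        sample_ids=[f"s{j}" for j in range(H.shape[1])],
    )


@pytest.fixture
def reference(rng):
    W = rng.random((50, 3)) + 0.05
    W[:8, 0] += 4
    W[8:16, 1] += 4
    W[16:24, 2] += 4
    return _compset(W, [f"g{i}" for i in range(50)])


class TestEstimateWeights:
    def test_pure_compartment_sample(self, reference):
        B = ExpressionMatrix(
            reference.W_final[:, [1]], reference.feature_ids, ["pure"]
        )
        est = estimate_weights(B, reference, normalize_subset=[0, 1, 2])[0]
        assert est.normalized_weights[1] > 0.99

    def test_exact_mixture_recovery(self, reference, rng):
        H_true = rng.random((3, 5))
        B = ExpressionMatrix(
            reference.W_final @ H_true,
            reference.feature_ids,
            [f"b{j}" for j in range(5)],
        )
        ests = estimate_weights(B, reference)
        H = np.column_stack([e.raw_weights for e in ests])
        np.testing.assert_allclose(H, H_true, atol=1e-6)
        assert all(e.n_genes_used == 50 for e in ests)

    def test_gene_dropout_shifts_weights_little(self, reference, rng):
        H_true = rng.dirichlet(np.ones(3), size=6).T
        full = ExpressionMatrix(
            reference.W_final @ H_true, reference.feature_ids,
            [f"b{j}" for j in range(6)],
        )
        keep = sorted(rng.choice(50, size=40, replace=False))
        dropped = ExpressionMatrix(
            full.values[keep], [reference.feature_ids[i] for i in keep],
            full.sample_ids,
        )
        e_full = estimate_weights(full, reference, normalize_subset=[0, 1, 2])
        e_drop = estimate_weights(dropped, reference, normalize_subset=[0, 1, 2])
        for a, b in zip(e_full, e_drop):
            np.testing.assert_allclose(
                a.normalized_weights, b.normalized_weights, atol=0.05
            )

    def test_sparse_feature_match_warns(self, reference, rng):
        keep = list(range(10))  # only 20% of reference features present
        B = ExpressionMatrix(
            reference.W_final[keep] @ rng.random((3, 2)),
            [reference.feature_ids[i] for i in keep],
            ["s1", "s2"],
        )
        with pytest.warns(UserWarning, match="matched"):
            estimate_weights(B, reference)

    def test_no_shared_features_error(self, reference):
        B = ExpressionMatrix(np.ones((2, 1)), ["x1", "x2"], ["s"])
        with pytest.raises(ValidationError, match="shared"):
            estimate_weights(B, reference)

    def test_training_samples_reproduce_denovo_H(self, reference, rng):
        # with a full-column-rank W and zero-residual samples, projecting
        # the training data itself returns the de novo weights exactly
        H = rng.random((3, 4)) + 0.1
        A = ExpressionMatrix(
            reference.W_final @ H, reference.feature_ids,
            [f"s{j}" for j in range(4)],
        )
        ests = estimate_weights(A, reference)
        np.testing.assert_allclose(
            np.column_stack([e.raw_weights for e in ests]), H, atol=1e-6
        )


class TestNormalize:
    def test_simple(self):
        out, flag = normalize_weights(np.array([2.0, 1.0, 1.0]), [0, 1, 2])
        np.testing.assert_allclose(out, [0.5, 0.25, 0.25])
        assert not flag

    def test_all_zero_flagged(self):
        out, flag = normalize_weights(np.zeros(3), [0, 2])
        np.testing.assert_allclose(out, 0.0)
        assert flag

    def test_scale_invariance_and_subset(self, rng):
        raw = rng.random(5)
        a, _ = normalize_weights(raw, [1, 3, 4])
        b, _ = normalize_weights(raw * 37.0, [1, 3, 4])
        np.testing.assert_allclose(a, b)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)


class TestBasalClassical:
    def test_boundary_is_basal(self):
        ratio, diff, call = basal_classical_metrics(np.array([0.3, 0.3]), 0, 1)
        assert ratio == pytest.approx(1.0) and call == "Basal-like"

    def test_classical_call(self):
        ratio, diff, call = basal_classical_metrics(np.array([0.1, 0.4]), 0, 1)
        assert ratio == pytest.approx(0.25)
        assert diff == pytest.approx(-0.3)
        assert call == "Classical"

    def test_zero_classical_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ratio, _, call = basal_classical_metrics(np.array([0.2, 0.0]), 0, 1)
        assert np.isinf(ratio) and call == "Basal-like"

    def test_missing_compartment_error(self):
        we = WeightEstimate("s", np.array([0.5]))
        with pytest.raises(ValidationError):
            basal_classical_metrics(we, 0, 3)


class TestTenfoldCV:
    def _denovo_factory(self, W_ref, feature_ids):
        # stand-in deconvolution: returns the fixed reference weights and
        # the NNLS projection of whatever samples it is given, so the CV
        # bookkeeping (folds, matching, correlations) is exercised cheaply
        from decompart.projection import project_compartment_weights
        from decompart.types import FilteredMatrix

        def denovo(mat):
            fm = FilteredMatrix(mat.values, mat.feature_ids, mat.sample_ids)
            H = project_compartment_weights(W_ref, fm)
            return _compset(W_ref, feature_ids, H=H), None

        return denovo

    def test_partition_and_agreement(self, rng):
        W = np.full((300, 3), 0.05)
        W[:100, 0] = 5.0
        W[100:200, 1] = 5.0
        W[200:, 2] = 5.0
        ids = [f"g{i}" for i in range(300)]
        H_true = rng.dirichlet(np.ones(3), size=20).T
        A = ExpressionMatrix(W @ H_true, ids, [f"s{j}" for j in range(20)])
        report = tenfold_cv(A, self._denovo_factory(W, ids), rng_seed=3)
        # every sample held out exactly once => all matched everywhere
        assert (report["n_samples_matched"] == 20).all()
        assert (report["pearson_r"] > 0.999).all()

    def test_reproducible_partition(self, rng):
        W = np.full((300, 2), 0.05)
        W[:150, 0] = 5.0
        W[150:, 1] = 5.0
        ids = [f"g{i}" for i in range(300)]
        A = ExpressionMatrix(
            W @ rng.dirichlet(np.ones(2), size=12).T, ids,
            [f"s{j}" for j in range(12)],
        )
        f = self._denovo_factory(W, ids)
        r1 = tenfold_cv(A, f, rng_seed=9)
        r2 = tenfold_cv(A, f, rng_seed=9)
        np.testing.assert_array_equal(
            r1["pearson_r"].to_numpy(), r2["pearson_r"].to_numpy()
        )

    def test_too_few_samples_error(self, rng):
        A = ExpressionMatrix(rng.random((5, 4)), list("abcde"), list("wxyz"))
        with pytest.raises(ValidationError):
            tenfold_cv(A, lambda m: (None, None))
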