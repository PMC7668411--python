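"""Sparse autoencoder: loss, gradients, pretraining, stacking, CV pipeline."""

import numpy as np
import pytest
from scipy.optimize import check_grad, minimize

from megsense import (
    AEConfig,
    DecoderConfig,
    ae_pipeline_eval,
    build_stack,
    encode,
    pretrain_layer,
    sparse_ae_loss,
)
from megsense.features import FeatureMatrix

from .conftest import make_planted_dataset

D_IN, D_H = 7, 4


def random_params(rng, d_in=D_IN, d_h=D_H, scale=0.3):
    n = d_h * d_in + d_h + d_in * d_h + d_in
    return scale * rng.standard_normal(n)


class TestLoss:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (11, D_IN))
        p0 = random_params(rng)
        err = check_grad(
            lambda p: sparse_ae_loss(p, X, D_H, 0.01, 2.0, 0.15)[0],
            lambda p: sparse_ae_loss(p, X, D_H, 0.01, 2.0, 0.15)[1],
            p0,
        )
        assert err < 1e-5

    def test_zero_coefficients_remove_their_terms_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (9, D_IN))
        p = random_params(rng)
        total, _, comps = sparse_ae_loss(p, X, D_H, 0.0, 0.0, 0.2)
        assert comps["l2"] == 0.0 and comps["kl"] == 0.0
        assert total == comps["mse"]
        total2, _, comps2 = sparse_ae_loss(p, X, D_H, 0.05, 3.0, 0.2)
        assert comps2["mse"] == comps["mse"]  # mse unaffected by regularisers
        assert total2 == pytest.approx(comps2["mse"] + comps2["l2"] + comps2["kl"])

    def test_kl_term_is_nonnegative(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (9, D_IN))
        for _ in range(10):
            _, _, comps = sparse_ae_loss(random_params(rng), X, D_H, 0.0, 4.0, 0.1)
            assert comps["kl"] >= 0.0


class TestPretrain:
    def test_repeated_vector_is_reconstructed_with_sparse_activations(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.uniform(0.2, 0.8, D_IN), (30, 1))
        (W1, b1), (W2, b2), hist = pretrain_layer(
            X, D_H, l2=0.0, beta=4.0, rho=0.1, max_epochs=300, seed=0
        )
        from megsense.autoencoder import _sigmoid

        H = _sigmoid(X @ W1.T + b1)
        Xhat = _sigmoid(H @ W2.T + b2)
        assert np.mean((X - Xhat) ** 2) < 1e-3
        assert H.max() < 0.999  # sparsity pressure keeps activations off the rail

    def test_plain_ae_matches_independent_mse_only_trainer(self):
        """With beta = lambda = 0 the loss is plain MSE; an independently coded
        finite-difference trainer reaches a comparable optimum."""
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (20, 5))
        _, _, hist = pretrain_layer(X, 3, l2=0.0, beta=0.0, rho=0.2,
                                    max_epochs=200, seed=0)

        def mse_only(p):  # independent forward pass; per-sample summed error
            i = 0
            W1 = p[i:i + 15].reshape(3, 5); i += 15
            b1 = p[i:i + 3]; i += 3
            W2 = p[i:i + 15].reshape(5, 3); i += 15
            b2 = p[i:i + 5]
            H = 1 / (1 + np.exp(-(X @ W1.T + b1)))
            Xhat = 1 / (1 + np.exp(-(H @ W2.T + b2)))
            return np.sum((X - Xhat) ** 2) / len(X)

        res = minimize(mse_only, 0.3 * rng.standard_normal(38), method="L-BFGS-B",
                       options={"maxiter": 300})
        assert hist["total"][-1] == pytest.approx(res.fun, abs=0.01)

    def test_loss_history_is_finite_and_converging(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (25, D_IN))
        _, _, hist = pretrain_layer(X, D_H, max_epochs=200, seed=1)
        total = np.array(hist["total"])
        assert np.isfinite(total).all()
        assert total[-1] <= total[0]
        tail = total[-max(2, len(total) // 10):]
        assert (np.diff(tail) <= 1e-6).all()

    def test_unscaled_data_rejected(self):
        with pytest.raises(ValueError, match="scaled"):
            pretrain_layer(np.random.default_rng(0).normal(5, 2, (10, 4)), 2)


@pytest.fixture(scope="module")
def small_stack():
    rng = np.random.default_rng(6)
    X = rng.uniform(0, 1, (45, 24))
    labels = np.repeat(np.arange(3), 15)
    cfg = AEConfig(layer_dims=(12, 8, 5), sparsity_proportion=(0.2, 0.15, 0.1),
                   max_epochs=80, finetune_epochs=80)
    return X, labels, build_stack(X, labels, cfg, seed=0)


class TestStack:
    def test_layer_dimension_cascade(self, small_stack):
        X, labels, stack = small_stack
        dims = [W.shape for W, _ in stack.encoder_weights]
        assert dims == [(12, 24), (8, 12), (5, 8)]
        assert stack.code_dim == 5

    def test_codes_lie_in_sigmoid_range(self, small_stack):
        X, _, stack = small_stack
        codes = stack.transform(X)
        assert (codes > 0).all() and (codes < 1).all()

    def test_encoding_is_rowwise(self, small_stack):
        X, _, stack = small_stack
        perm = np.random.default_rng(1).permutation(len(X))
        assert np.allclose(stack.transform(X[perm]), stack.transform(X)[perm])

    def test_different_seeds_give_different_weights(self, small_stack):
        X, labels, stack = small_stack
        other = build_stack(X, labels, stack.config, seed=99)
        assert not np.allclose(stack.encoder_weights[0][0], other.encoder_weights[0][0])

    def test_same_seed_is_deterministic(self, small_stack):
        X, labels, stack = small_stack
        again = build_stack(X, labels, stack.config, seed=0)
        assert np.array_equal(stack.encoder_weights[0][0], again.encoder_weights[0][0])

    def test_encode_checks_dimensions(self, small_stack):
        _, _, stack = small_stack
        fm = FeatureMatrix(np.zeros((2, 6)), np.zeros(2, int), ["MEG0012"])
        with pytest.raises(ValueError, match="dim"):
            encode(stack, fm)

    def test_nondecreasing_dims_rejected(self):
        with pytest.raises(ValueError):
            AEConfig(layer_dims=(10, 10, 5))


class TestPipeline:
    def test_embedding_separates_strong_classes(self):
        """Centroid separation (relative to scatter) improves in code space."""
        _, _, _, fm = make_planted_dataset(
            n_sensors=6, n_classes=2, n_per_class=15, n_informative=2,
            amplitude=5.0, seed=8,
        )
        cfg = AEConfig(layer_dims=(18, 10, 6), sparsity_proportion=(0.2, 0.15, 0.1),
                       max_epochs=150, finetune_epochs=150)
        stack = build_stack(fm, config=cfg, seed=0)
        emb = encode(stack, fm)

        def separation(values, labels):
            c0, c1 = (values[labels == k].mean(axis=0) for k in (0, 1))
            scatter = np.mean([values[labels == k].std(axis=0).mean() for k in (0, 1)])
            return np.linalg.norm(c0 - c1) / scatter

        # normalise input the same way the stack does before comparing
        lo, rng_ = stack.scaler
        sep_in = separation((fm.values - lo) / rng_, fm.labels)
        sep_code = separation(emb.values, emb.labels)
        assert sep_code > sep_in

    def test_cv_pipeline_returns_fold_sizes_and_chance_on_noise(self):
        _, _, _, fm = make_planted_dataset(
            n_sensors=4, n_classes=2, n_per_class=10, n_informative=2,
            amplitude=0.0, seed=9,
        )
        cfg = AEConfig(layer_dims=(12, 8, 4), sparsity_proportion=(0.2, 0.15, 0.1),
                       max_epochs=40, finetune_epochs=40)
        res = ae_pipeline_eval(fm, cfg, DecoderConfig(folds=5, seed=0))
        assert len(res.fold_accuracies) == 5
        assert res.confusion.sum() == fm.n_trials
        assert res.mean_accuracy < 85.0  # no signal planted: far from ceiling
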