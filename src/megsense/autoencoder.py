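"""Stacked sparse autoencoder for band-power feature dimension reduction.

Three shallow autoencoders with logistic-sigmoid encoder and decoder are
pretrained greedily (each on the previous layer's codes) and then stacked
and fine-tuned with a softmax head on the class labels; the 54-dimensional
embedding — the feature size of 9 sensors — then feeds the SVM decoder.

Each autoencoder minimises the sparse reconstruction loss

    L = MSE(x, xhat) + (lambda/2) * ||W||^2 + beta * sum_j KL(rho || rhohat_j)

where ``rhohat_j`` is the mean activation of hidden unit j over the batch
and KL is the Bernoulli Kullback-Leibler divergence pulling average
activations towards the target sparsity proportion ``rho``. Gradients are
analytic and optimisation is full-batch L-BFGS; the loss, not the
optimiser, defines the method, and any full-batch optimiser satisfying the
monotone-convergence contract is admissible.

Inputs are min-max scaled to [0, 1] (fit on training rows only) so the
sigmoid decoder's range covers its targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .decode import CVResult, DecoderConfig, crossval_svm, make_folds
from .features import FeatureMatrix

__all__ = [
    "AEConfig",
    "StackedAE",
    "sparse_ae_loss",
    "pretrain_layer",
    "build_stack",
    "encode",
    "ae_pipeline_eval",
]

_EPS = 1e-8


@dataclass
class AEConfig:
    """Stacked-AE architecture and regularisation hyperparameters.

    ``layer_dims`` excludes the input layer; defaults to the 600/300/54
    cascade (each hidden layer roughly half the previous, the last equal to
    the feature size of 9 sensors). ``l2_coeff`` defaults to the middle of
    the 0.001-0.004 grid found adequate per subject.
    """

    layer_dims: tuple[int, ...] = (600, 300, 54)
    l2_coeff: float | tuple[float, ...] = 0.002
    sparsity_reg: float = 4.0
    sparsity_proportion: tuple[float, ...] = (0.20, 0.15, 0.10)
    max_epochs: int = 400
    finetune_epochs: int = 200
    finetune_l2: float = 1e-4
    #: "per_column_minmax" maps each column into [0,1] (the default;
    #: sigmoid-range targets per feature); "global_minmax" uses one affine
    #: transform for the whole matrix, preserving relative column variances
    #: at the cost of resolution when a few columns dominate the range
    input_scaling: str = "per_column_minmax"

    def __post_init__(self) -> None:
        dims = tuple(self.layer_dims)
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError("hidden dims must be strictly decreasing")
        if any(not 0 < p < 1 for p in self.sparsity_proportion):
            raise ValueError("sparsity proportions must be in (0, 1)")
        if self.sparsity_reg < 0 or self.finetune_l2 < 0:
            raise ValueError("regularisation coefficients must be >= 0")
        if self.input_scaling not in ("global_minmax", "per_column_minmax"):
            raise ValueError(
                "input_scaling must be 'global_minmax' or 'per_column_minmax'"
            )
        if len(self.sparsity_proportion) != len(dims):
            raise ValueError("one sparsity proportion per layer required")

    def l2_for_layer(self, i: int) -> float:
        if np.isscalar(self.l2_coeff):
            return float(self.l2_coeff)
        return float(self.l2_coeff[i])


@dataclass
class StackedAE:
    """Trained encoder stack with per-layer decoders and a softmax head."""

    encoder_weights: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    decoder_weights: list[tuple[np.ndarray, np.ndarray]]
    softmax_weights: tuple[np.ndarray, np.ndarray]
    scaler: tuple[np.ndarray, np.ndarray]  # per-column (min, range) of training data
    classes: np.ndarray
    config: AEConfig
    history: dict = field(default_factory=dict)

    @property
    def code_dim(self) -> int:
        return self.encoder_weights[-1][0].shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Forward pass through the scaler and encoder stack (no labels used)."""
        lo, rng = self.scaler
        Z = (np.asarray(X, dtype=np.float64) - lo) / rng
        for W, b in self.encoder_weights:
            Z = _sigmoid(Z @ W.T + b)
        return Z


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unpack(params: np.ndarray, d_in: int, d_h: int):
    i = 0
    W1 = params[i : i + d_h * d_in].reshape(d_h, d_in); i += d_h * d_in
    b1 = params[i : i + d_h]; i += d_h
    W2 = params[i : i + d_in * d_h].reshape(d_in, d_h); i += d_in * d_h
    b2 = params[i : i + d_in]
    return W1, b1, W2, b2


def sparse_ae_loss(
    params: np.ndarray,
    X: np.ndarray,
    d_hidden: int,
    l2: float,
    beta: float,
    rho: float,
) -> tuple[float, np.ndarray, dict]:
    """Sparse-AE loss, analytic gradient and the individual loss terms.

    The reconstruction term is the squared error summed over feature
    dimensions and averaged over samples — the convention under which the
    usual sparse-AE hyperparameter ranges (lambda ~ 1e-3, beta ~ 1-4) are
    balanced; an element-wise mean would shrink it by d_in and let the
    sparsity penalty collapse the code to a constant.

    Returns ``(total, grad, components)`` where components holds the ``mse``,
    ``l2`` and ``kl`` terms separately; a zero coefficient removes its term
    exactly.
    """
    n, d_in = X.shape
    W1, b1, W2, b2 = _unpack(params, d_in, d_hidden)
    H = _sigmoid(X @ W1.T + b1)
    Xhat = _sigmoid(H @ W2.T + b2)

    resid = Xhat - X
    mse = float(np.sum(resid**2) / n)
    l2_term = 0.5 * l2 * float(np.sum(W1**2) + np.sum(W2**2)) if l2 else 0.0
    if beta:
        rho_hat = np.clip(H.mean(axis=0), _EPS, 1 - _EPS)
        kl_term = beta * float(
            np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
        )
    else:
        rho_hat = None
        kl_term = 0.0
    total = mse + l2_term + kl_term

    # backprop
    delta2 = resid * Xhat * (1 - Xhat) * (2.0 / n)
    gW2 = delta2.T @ H
    gb2 = delta2.sum(axis=0)
    dH = delta2 @ W2
    if beta:
        dH = dH + (beta / n) * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat))
    delta1 = dH * H * (1 - H)
    gW1 = delta1.T @ X
    gb1 = delta1.sum(axis=0)
    if l2:
        gW1 += l2 * W1
        gW2 += l2 * W2
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return total, grad, {"mse": mse, "l2": l2_term, "kl": kl_term}


def _init_layer(rng: np.random.Generator, d_out: int, d_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot for sigmoid units
    return rng.uniform(-bound, bound, (d_out, d_in))


def pretrain_layer(
    data: np.ndarray,
    d_hidden: int,
    l2: float = 0.002,
    beta: float = 4.0,
    rho: float = 0.2,
    max_epochs: int = 400,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], dict]:
    """Train one sparse autoencoder layer; returns encoder, decoder and history.

    ``data`` must lie in [0, 1]. The history records the total loss and its
    mse/l2/kl components at each accepted L-BFGS iterate; the final loss
    never exceeds the initial one.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("data must be rows x features")
    if X.min() < -1e-9 or X.max() > 1 + 1e-9:
        raise ValueError("data must be scaled to [0, 1] before pretraining")
    n, d_in = X.shape
    if n < d_hidden:
        import warnings

        warnings.warn(
            f"{n} rows < {d_hidden} hidden units; layer may overfit", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    params0 = np.concatenate(
        [
            _init_layer(rng, d_hidden, d_in).ravel(),
            np.zeros(d_hidden),
            _init_layer(rng, d_in, d_hidden).ravel(),
            np.zeros(d_in),
        ]
    )
    history: dict[str, list[float]] = {"total": [], "mse": [], "l2": [], "kl": []}

    def objective(p):
        total, grad, _ = sparse_ae_loss(p, X, d_hidden, l2, beta, rho)
        return total, grad

    def record(p):
        total, _, comps = sparse_ae_loss(p, X, d_hidden, l2, beta, rho)
        history["total"].append(total)
        for k, v in comps.items():
            history[k].append(v)

    record(params0)
    res = minimize(
        objective,
        params0,
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_epochs, "maxcor": 20},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"pretraining diverged: loss={res.fun}, status={res.message}")
    W1, b1, W2, b2 = _unpack(res.x, d_in, d_hidden)
    return (W1, b1), (W2, b2), history


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _finetune(
    X01: np.ndarray,
    y_onehot: np.ndarray,
    layers: list[tuple[np.ndarray, np.ndarray]],
    softmax_wb: tuple[np.ndarray, np.ndarray],
    l2: float,
    max_epochs: int,
) -> tuple[list, tuple, list[float]]:
    """Supervised fine-tune of the whole stack + softmax head (cross-entropy)."""
    shapes = [(W.shape, b.shape) for W, b in layers] + [
        (softmax_wb[0].shape, softmax_wb[1].shape)
    ]

    def pack(lay, sm):
        return np.concatenate(
            [np.concatenate([W.ravel(), b]) for W, b in lay + [sm]]
        )

    def unpack(p):
        out = []
        i = 0
        for (ws, bs) in shapes:
            W = p[i : i + np.prod(ws)].reshape(ws); i += np.prod(ws)
            b = p[i : i + bs[0]]; i += bs[0]
            out.append((W, b))
        return out[:-1], out[-1]

    n = X01.shape[0]

    def objective(p):
        lay, (Ws, bs) = unpack(p)
        acts = [X01]
        for W, b in lay:
            acts.append(_sigmoid(acts[-1] @ W.T + b))
        P = _softmax(acts[-1] @ Ws.T + bs)
        ce = -float(np.mean(np.sum(y_onehot * np.log(P + _EPS), axis=1)))
        l2_term = 0.5 * l2 * (sum(float(np.sum(W**2)) for W, _ in lay) + float(np.sum(Ws**2)))
        # backprop
        grads = []
        dlogits = (P - y_onehot) / n
        gWs = dlogits.T @ acts[-1] + l2 * Ws
        gbs = dlogits.sum(axis=0)
        d = dlogits @ Ws
        for li in range(len(lay) - 1, -1, -1):
            W, _b = lay[li]
            a = acts[li + 1]
            delta = d * a * (1 - a)
            gW = delta.T @ acts[li] + l2 * W
            gb = delta.sum(axis=0)
            grads.append((gW, gb))
            d = delta @ W
        grads.reverse()
        gflat = pack(grads, (gWs, gbs))
        return ce + l2_term, gflat

    history: list[float] = []

    def record(p):
        history.append(objective(p)[0])

    p0 = pack(list(layers), softmax_wb)
    record(p0)
    res = minimize(
        objective, p0, jac=True, method="L-BFGS-B",
        callback=record, options={"maxiter": max_epochs, "maxcor": 20},
    )
    lay, sm = unpack(res.x)
    return lay, sm, history


def build_stack(
    train_features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    config: AEConfig | None = None,
    seed: int = 0,
) -> StackedAE:
    """Greedy layer-wise pretraining followed by supervised fine-tuning.

    Layer 1 trains on the (min-max scaled) inputs, layer 2 on layer-1 codes,
    layer 3 on layer-2 codes; the stacked encoders plus a softmax head are
    then fine-tuned on the labels. Deterministic given ``seed``.
    """
    if config is None:
        config = AEConfig()
    if isinstance(train_features, FeatureMatrix):
        X = np.asarray(train_features.values, dtype=np.float64)
        if labels is None:
            labels = train_features.labels
    else:
        X = np.asarray(train_features, dtype=np.float64)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
    labels = np.asarray(labels)

    if config.input_scaling == "global_minmax":
        lo = np.full(X.shape[1], X.min())
        rng_ = np.full(X.shape[1], max(X.max() - X.min(), _EPS))
    else:
        lo = X.min(axis=0)
        rng_ = np.maximum(X.max(axis=0) - lo, _EPS)
    Z = (X - lo) / rng_

    encoders: list[tuple[np.ndarray, np.ndarray]] = []
    decoders: list[tuple[np.ndarray, np.ndarray]] = []
    history: dict = {"pretrain": []}
    codes = Z
    for i, d_h in enumerate(config.layer_dims):
        enc, dec, hist = pretrain_layer(
            codes,
            d_h,
            l2=config.l2_for_layer(i),
            beta=config.sparsity_reg,
            rho=config.sparsity_proportion[i],
            max_epochs=config.max_epochs,
            seed=seed + i,
        )
        encoders.append(enc)
        decoders.append(dec)
        history["pretrain"].append(hist)
        codes = _sigmoid(codes @ enc[0].T + enc[1])

    classes = np.unique(labels)
    y_onehot = (labels[:, None] == classes[None, :]).astype(float)
    rng = np.random.default_rng(seed + 100)
    sm0 = (
        _init_layer(rng, len(classes), config.layer_dims[-1]),
        np.zeros(len(classes)),
    )
    encoders, sm, ft_hist = _finetune(
        Z, y_onehot, encoders, sm0, config.finetune_l2, config.finetune_epochs
    )
    history["finetune"] = ft_hist
    return StackedAE(
        encoder_weights=encoders,
        decoder_weights=decoders,
        softmax_weights=sm,
        scaler=(lo, rng_),
        classes=classes,
        config=config,
        history=history,
    )


def encode(stack: StackedAE, features: FeatureMatrix) -> FeatureMatrix:
    """Embed a feature matrix through the encoder stack (row-wise, label-free)."""
    d_in = stack.encoder_weights[0][0].shape[1]
    if features.n_features != d_in:
        raise ValueError(
            f"feature dim {features.n_features} does not match stack input {d_in}"
        )
    codes = stack.transform(features.values)
    return FeatureMatrix(
        codes,
        features.labels.copy(),
        [f"z{j:02d}" for j in range(codes.shape[1])],
        bands=("code",),
    )


def ae_pipeline_eval(
    features: FeatureMatrix,
    ae_config: AEConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    fold_assignment: np.ndarray | None = None,
    refit_per_fold: bool = True,
) -> CVResult:
    """Cross-validated SVM decoding of AE-embedded features.

    By default the autoencoder (scaler, pretraining and fine-tuning) is
    refit on each fold's training rows only and both splits are then
    encoded; ``refit_per_fold=False`` fits one stack on the first fold's
    training rows and reuses it (single-split mode).
    """
    if ae_config is None:
        ae_config = AEConfig()
    if decoder_config is None:
        decoder_config = DecoderConfig()
    y = np.asarray(features.labels)
    if fold_assignment is None:
        fold_assignment = make_folds(y, decoder_config.folds, decoder_config.seed)
    n_folds = int(fold_assignment.max()) + 1
    X = np.asarray(features.values, dtype=np.float64)
    classes = np.unique(y)
    from sklearn.metrics import confusion_matrix

    accs = np.empty(n_folds)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    stack = None
    for f in range(n_folds):
        test = np.flatnonzero(fold_assignment == f)
        train = np.flatnonzero(fold_assignment != f)
        if refit_per_fold or stack is None:
            stack = build_stack(
                X[train], y[train], ae_config, seed=decoder_config.seed + f
            )
        emb_train = FeatureMatrix(
            stack.transform(X[train]), y[train],
            [f"z{j:02d}" for j in range(stack.code_dim)], bands=("code",),
        )
        emb_test_vals = stack.transform(X[test])
        from .decode import _fit_predict_fold

        both = np.vstack([emb_train.values, emb_test_vals])
        yy = np.concatenate([y[train], y[test]])
        pred = _fit_predict_fold(
            both, yy, np.arange(len(train)), np.arange(len(train), len(yy)),
            decoder_config,
        )
        accs[f] = 100.0 * np.mean(pred == y[test])
        confusion += confusion_matrix(y[test], pred, labels=classes)
    return CVResult(accs, confusion, fold_assignment, classes)
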