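"""Stacked-CAE deep belief network classifier.

The network is assembled from greedily pretrained continuous autoencoders
and one output layer, then fine-tuned end-to-end with momentum, dropout on
the hidden layers, and the same early-break rule as the optimiser module.

With the default layer sizes (42, 10, 42, 8, 42, 19) the stack unrolls to
five weight matrices: the first CAE spans 42 -> 10 -> 42, the second
42 -> 8 -> 42, and the output layer maps the last 42 units onto the 19
class units.  Class targets are one-of-N codes affinely mapped into the
activation's output range; inputs are min-max scaled into the same range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn_core, optim
from .nn_core import (ActivationConfig, CAE, CAEParams, LossConfig,
                      activation_deriv, improved_sigmoid)

__all__ = [
    "DBNSpec",
    "DBNModel",
    "FeatureScaler",
    "MultilayerNet",
    "fit_scaler",
    "pretrain_stack",
    "finetune",
    "predict",
]


# ---------------------------------------------------------------------------
# input scaling
# ---------------------------------------------------------------------------


@dataclass
class FeatureScaler:
    """Min-max map of raw features into the activation output range.

    ``transform`` sends [lo, hi] per dimension onto [-0.5 k, 0.5 k]; the
    map round-trips exactly through ``inverse``.
    """

    lo: np.ndarray
    hi: np.ndarray
    k: float = 1.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.hi - self.lo
        span = np.where(span == 0, 1.0, span)
        return self.k * ((X - self.lo) / span - 0.5)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        span = np.where(self.hi - self.lo == 0, 1.0, self.hi - self.lo)
        return (np.asarray(Z, dtype=float) / self.k + 0.5) * span + self.lo


def fit_scaler(features: np.ndarray, act: ActivationConfig) -> FeatureScaler:
    F = np.atleast_2d(np.asarray(features, dtype=float))
    return FeatureScaler(lo=F.min(axis=0), hi=F.max(axis=0), k=act.k)


# ---------------------------------------------------------------------------
# shared multilayer forward/backward
# ---------------------------------------------------------------------------


def _forward(weights, X, act: ActivationConfig, rng=None,
             dropout_rate: float = 0.0, train: bool = False):
    """Forward pass; returns (pre-activations, activations, dropout masks).

    Gaussian units perturb every pre-activation while training; dropout
    (inverted scaling) masks hidden-layer outputs only.
    """
    pre, hs, masks = [], [np.atleast_2d(X)], []
    h = hs[0]
    last = len(weights) - 1
    for li, (W, b) in enumerate(weights):
        a = h @ W.T + b
        if train and act.sigma > 0:
            a = a + act.sigma * rng.standard_normal(a.shape)
        h = improved_sigmoid(a, act)
        if train and dropout_rate > 0 and li < last:
            mask = rng.random(h.shape) >= dropout_rate
            h = h * mask / (1.0 - dropout_rate)
            masks.append(mask)
        else:
            masks.append(None)
        pre.append(a)
        hs.append(h)
    return pre, hs, masks


def _backward(weights, pre, hs, masks, T, act: ActivationConfig,
              lambda_decay: float, dropout_rate: float):
    """Exact gradients of mean 0.5*||out - T||^2 (+ weight decay)."""
    m = T.shape[0]
    grads = [None] * len(weights)
    delta = (hs[-1] - T) * activation_deriv(pre[-1], act) / m
    for li in range(len(weights) - 1, -1, -1):
        W, _ = weights[li]
        dW = delta.T @ hs[li] + lambda_decay * W
        db = delta.sum(axis=0)
        grads[li] = (dW, db)
        if li > 0:
            delta = delta @ W
            if masks[li - 1] is not None:
                delta = delta * masks[li - 1] / (1.0 - dropout_rate)
            delta = delta * activation_deriv(pre[li - 1], act)
    return grads


def _init_layer(n_out: int, n_in: int, rng: np.random.Generator):
    r = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-r, r, size=(n_out, n_in)), np.zeros(n_out)


class MultilayerNet:
    """A plain stack of improved-sigmoid layers, trainable per sample.

    Used for the swiss-roll reconstruction demo (e.g. sizes 3-16-2-16-3)
    and as the unrolled form of a fine-tuned DBN.  Satisfies the optimiser
    protocol (``parameters`` / ``sample_gradients`` / ``batch_loss``).
    """

    def __init__(self, sizes, act: ActivationConfig | None = None,
                 loss_cfg: LossConfig | None = None, seed=0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.sizes = tuple(int(s) for s in sizes)
        self.act = act if act is not None else ActivationConfig()
        self.loss_cfg = loss_cfg if loss_cfg is not None else LossConfig()
        self.weights = [
            list(_init_layer(self.sizes[i + 1], self.sizes[i], rng))
            for i in range(len(self.sizes) - 1)
        ]

    def parameters(self) -> list[np.ndarray]:
        return [arr for layer in self.weights for arr in layer]

    def forward(self, X: np.ndarray, rng=None, train: bool = False) -> np.ndarray:
        _, hs, _ = _forward(self.weights, X, self.act, rng, 0.0,
                            train and self.act.train_mode)
        return hs[-1]

    def batch_loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        out = self.forward(X)
        data = 0.5 * float(np.mean(np.sum((out - np.atleast_2d(Y)) ** 2, axis=1)))
        decay = 0.5 * self.loss_cfg.lambda_decay * sum(
            float(np.sum(W ** 2)) for W, _ in self.weights)
        return data + decay

    def sample_gradients(self, x, y, rng) -> list[np.ndarray]:
        X = np.atleast_2d(x)
        T = np.atleast_2d(y)
        train = self.act.train_mode and self.act.sigma > 0
        pre, hs, masks = _forward(self.weights, X, self.act, rng, 0.0, train)
        grads = _backward(self.weights, pre, hs, masks, T, self.act,
                          self.loss_cfg.lambda_decay, 0.0)
        return [arr for g in grads for arr in g]


# ---------------------------------------------------------------------------
# DBN spec / model
# ---------------------------------------------------------------------------


def _default_pretrain() -> optim.FSGDConfig:
    return optim.FSGDConfig(n=30, alpha=0.1, epsilon=0.003, K=5)


def _default_finetune_break() -> optim.FSGDConfig:
    return optim.FSGDConfig(n=100, alpha=0.6, epsilon=0.002, K=10)


@dataclass
class DBNSpec:
    """Architecture and training hyperparameters of the classifier.

    ``layer_sizes`` must chain as V, H0, H1, H2, H3, ..., T where every
    other entry from index 0 repeats the CAE visible width (each CAE is
    v -> h -> v); the final entry is the class count.  ``fsgd`` only
    contributes the fine-tuning break rule (epsilon, K, consecutive);
    the fine-tuning step size is ``learning_rate``.
    """

    layer_sizes: tuple[int, ...] = (42, 10, 42, 8, 42, 19)
    learning_rate: float = 0.6
    momentum: float = 0.06
    dropout_rate: float = 0.1
    epochs: int = 100
    batch_size: int = 32
    # steeper activation keeps gradients alive through the 5-layer stack
    act: ActivationConfig = field(default_factory=lambda: ActivationConfig(c=3.0, sigma=0.02))
    loss: LossConfig = field(default_factory=LossConfig)
    pretrain: optim.FSGDConfig | None = field(default_factory=_default_pretrain)
    fsgd: optim.FSGDConfig = field(default_factory=_default_finetune_break)

    def __post_init__(self) -> None:
        sizes = tuple(self.layer_sizes)
        if len(sizes) < 4 or len(sizes) % 2 != 0:
            raise ValueError("layer_sizes must be V, (h, V)*, T with >=1 CAE")
        for i in range(self.n_caes):
            if sizes[2 * i] != sizes[2 * i + 2]:
                raise ValueError(
                    "each CAE must reconstruct its own visible width "
                    f"(sizes[{2 * i}] != sizes[{2 * i + 2}])")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        self.layer_sizes = sizes

    @property
    def n_caes(self) -> int:
        return (len(self.layer_sizes) - 2) // 2

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]


@dataclass
class DBNModel:
    """Fine-tuned classifier: unrolled weights + codebook + input scaling."""

    weights: list  # [(W, b), ...] in forward order
    act: ActivationConfig
    classes: np.ndarray          # sorted class labels; index = output unit
    scaler: FeatureScaler
    loss: LossConfig = field(default_factory=LossConfig)
    history: optim.TrainHistory | None = None

    @property
    def label_codebook(self) -> dict:
        return {lab: i for i, lab in enumerate(self.classes)}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def pretrain_stack(features: np.ndarray, spec: DBNSpec, seed: int = 0
                   ) -> list[CAEParams]:
    """Greedy unsupervised pretraining of the CAE stack.

    The first CAE trains to reconstruct the (scaled) inputs; each further
    CAE trains on the previous CAE's reconstruction-layer activations,
    which share the visible width.  Returns one parameter set per CAE.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != spec.layer_sizes[0]:
        raise ValueError(
            f"feature dim {F.shape[1]} != input layer {spec.layer_sizes[0]}")
    scaler = fit_scaler(F, spec.act)
    X = scaler.transform(F)
    seeds = _spawn_seeds(seed, 2 * spec.n_caes)
    train_act = ActivationConfig(spec.act.k, spec.act.c, spec.act.sigma,
                                 train_mode=True,
                                 plain_sigmoid=spec.act.plain_sigmoid)
    stack: list[CAEParams] = []
    for i in range(spec.n_caes):
        visible = spec.layer_sizes[2 * i]
        hidden = spec.layer_sizes[2 * i + 1]
        cae = CAE.new(visible, hidden, train_act, spec.loss,
                      seed=seeds[2 * i])
        if spec.pretrain is not None:
            cfg = optim.FSGDConfig(
                n=spec.pretrain.n, alpha=spec.pretrain.alpha,
                epsilon=spec.pretrain.epsilon, K=spec.pretrain.K,
                seed=seeds[2 * i + 1], monitor=spec.pretrain.monitor,
                holdout_fraction=spec.pretrain.holdout_fraction,
                consecutive=spec.pretrain.consecutive)
            optim.fsgd_train(cae, X, cfg=cfg)
        stack.append(cae.params)
        # reconstruction-layer activations feed the next CAE (noise off)
        X = nn_core.reconstruct(X, CAEParams(
            cae.params.W_enc, cae.params.b_enc,
            cae.params.W_dec, cae.params.b_dec, spec.act.eval_mode()))
    return stack


def _one_hot_targets(labels, classes, act: ActivationConfig) -> np.ndarray:
    codebook = {lab: i for i, lab in enumerate(classes)}
    idx = np.array([codebook[lab] for lab in labels])
    T01 = np.eye(len(classes))[idx]
    return nn_core.to_activation_range(T01, act)


def finetune(stack: list[CAEParams], features: np.ndarray, labels,
             spec: DBNSpec, seed: int = 0) -> DBNModel:
    """Supervised end-to-end backprop over the unrolled stack + output layer.

    Velocity update ``v <- momentum*v - alpha*grad; theta <- theta + v``;
    inverted-scaling dropout on hidden layers while training; stops on the
    fine-tuning break rule (default epsilon=0.002, K=10) or at ``epochs``.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != F.shape[0]:
        raise ValueError("one label per feature row required")
    classes = np.unique(labels)
    if len(classes) != spec.n_classes:
        raise ValueError(
            f"found {len(classes)} classes but output layer has {spec.n_classes} units")

    scaler = fit_scaler(F, spec.act)
    X = scaler.transform(F)
    T = _one_hot_targets(labels, classes, spec.act)

    seeds = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(seeds[0])
    weights = []
    for p in stack:
        weights.append([p.W_enc.copy(), p.b_enc.copy()])
        weights.append([p.W_dec.copy(), p.b_dec.copy()])
    weights.append(list(_init_layer(spec.n_classes, spec.layer_sizes[-2], rng)))

    vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    brk = optim.EarlyBreak(spec.fsgd.epsilon, spec.fsgd.K, spec.fsgd.consecutive)
    history = optim.TrainHistory(seed=seed)
    train_act = ActivationConfig(spec.act.k, spec.act.c, spec.act.sigma,
                                 train_mode=True,
                                 plain_sigmoid=spec.act.plain_sigmoid)
    m = X.shape[0]
    bs = max(1, spec.batch_size)
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(m)
        for start in range(0, m, bs):
            sel = order[start:start + bs]
            pre, hs, masks = _forward(weights, X[sel], train_act, rng,
                                      spec.dropout_rate, train=True)
            grads = _backward(weights, pre, hs, masks, T[sel], train_act,
                              spec.loss.lambda_decay, spec.dropout_rate)
            for (W, b), (vW, vb), (gW, gb) in zip(weights, vel, grads):
                vW *= spec.momentum
                vW -= spec.learning_rate * gW
                W += vW
                vb *= spec.momentum
                vb -= spec.learning_rate * gb
                b += vb
        _, hs, _ = _forward(weights, X, spec.act.eval_mode())
        data = 0.5 * float(np.mean(np.sum((hs[-1] - T) ** 2, axis=1)))
        decay = 0.5 * spec.loss.lambda_decay * sum(
            float(np.sum(W ** 2)) for W, _ in weights)
        loss = data + decay
        history.losses.append(loss)
        history.break_epoch = epoch
        if brk.update(loss):
            history.broke_early = True
            break
    return DBNModel(weights=weights, act=spec.act.eval_mode(),
                    classes=classes, scaler=scaler, loss=spec.loss,
                    history=history)


def predict(model: DBNModel, features: np.ndarray):
    """Deterministic forward pass; argmax class (ties -> lowest index).

    Returns ``(labels, scores)`` where scores are the output-unit
    activations mapped back to the [0, 1] scale.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != model.weights[0][0].shape[1]:
        raise ValueError("feature dimension does not match the model")
    X = model.scaler.transform(F)
    _, hs, _ = _forward(model.weights, X, model.act.eval_mode())
    scores = nn_core.from_activation_range(hs[-1], model.act)
    idx = np.argmax(scores, axis=1)
    return model.classes[idx], scores
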