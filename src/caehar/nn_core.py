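"""Core neural-network primitives.

Implements the zero-centred, gain/steepness-parameterised sigmoid activation
with additive Gaussian stochastic units, the single-hidden-layer continuous
autoencoder (CAE) built from it, the squared-error + weight-decay loss
family, and exact analytic gradients.

Activation: ``f(a) = k * (1 / (1 + exp(-c * a)) - 0.5)``, optionally with
``a`` perturbed by ``sigma * N(0, 1)`` per unit while training.  The output
range is the open interval ``(-0.5 k, 0.5 k)``, so training targets living
in ``[0, 1]`` are affinely mapped into that range (see
:func:`to_activation_range`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ActivationConfig",
    "CAEParams",
    "CAEGrads",
    "LossConfig",
    "CAE",
    "improved_sigmoid",
    "activation_deriv",
    "taylor_reference",
    "noisy_preactivation",
    "encode",
    "decode",
    "reconstruct",
    "sample_loss",
    "total_loss",
    "gradients",
    "init_params",
    "to_activation_range",
    "from_activation_range",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class ActivationConfig:
    """Parameters of the stochastic activation unit.

    Parameters
    ----------
    k : float
        Gain control; scales the output range to ``(-0.5 k, 0.5 k)``.
    c : float
        Steepness control; scales the near-zero linear slope to ``k c / 4``.
    sigma : float
        Standard deviation of the additive Gaussian unit on the
        pre-activation.  Only active while ``train_mode`` is set.
    train_mode : bool
        When False the activation is fully deterministic.
    plain_sigmoid : bool
        Compatibility switch: ignore ``k``/``c`` and evaluate the standard
        logistic ``1 / (1 + exp(-a))`` so the model reduces bit-exactly to a
        basic autoencoder.
    """

    k: float = 1.0
    c: float = 1.0
    sigma: float = 0.1
    train_mode: bool = False
    plain_sigmoid: bool = False

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.c > 0):
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def eval_mode(self) -> "ActivationConfig":
        """A deterministic copy (noise off)."""
        return ActivationConfig(self.k, self.c, self.sigma, False,
                                self.plain_sigmoid)


@dataclass
class LossConfig:
    """Weight-decay coefficient for the regularised loss."""

    lambda_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be >= 0")


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------


def improved_sigmoid(a, act: ActivationConfig):
    """Zero-centred scaled sigmoid, elementwise.

    Returns ``k * (expit(c * a) - 0.5)``, evaluated as
    ``0.5 k tanh(c a / 2)`` so odd symmetry holds bitwise; output is kept
    strictly inside ``(-0.5 k, 0.5 k)`` (saturated values are pulled in by
    one ulp).  Raises on non-finite input.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite pre-activation")
    if act.plain_sigmoid:
        return expit(a)
    half = 0.5 * act.k
    out = half * np.tanh(0.5 * act.c * a)
    return np.clip(out, np.nextafter(-half, 0.0), np.nextafter(half, 0.0))


def activation_deriv(a, act: ActivationConfig):
    """Derivative of :func:`improved_sigmoid` w.r.t. its argument.

    With ``s = expit(c a)`` this is ``k * c * s * (1 - s)``.
    """
    a = np.asarray(a, dtype=float)
    if act.plain_sigmoid:
        s = expit(a)
        return s * (1.0 - s)
    s = expit(act.c * a)
    return act.k * act.c * s * (1.0 - s)


_TAYLOR_COEFF = {1: (0.25,), 3: (0.25, -1.0 / 48.0), 5: (0.25, -1.0 / 48.0, 1.0 / 480.0)}


def taylor_reference(a: float, act: ActivationConfig, order: int = 5) -> float:
    """Odd Taylor polynomial of the activation about 0.

    ``k * [c a / 4 - (c a)^3 / 48 + (c a)^5 / 480]`` truncated at `order`
    (1, 3 or 5).  Serves as an independent oracle for
    :func:`improved_sigmoid` near the origin; the remainder is O(a^7).
    """
    if order not in _TAYLOR_COEFF:
        raise ValueError(f"order must be one of 1, 3, 5; got {order}")
    u = act.c * float(a)
    total = 0.0
    for i, coef in enumerate(_TAYLOR_COEFF[order]):
        total += coef * u ** (2 * i + 1)
    return act.k * total


def to_activation_range(y, act: ActivationConfig):
    """Affine map from ``[0, 1]`` targets into the output range ``[-0.5k, 0.5k]``."""
    if act.plain_sigmoid:
        return np.asarray(y, dtype=float)
    return act.k * (np.asarray(y, dtype=float) - 0.5)


def from_activation_range(h, act: ActivationConfig):
    """Inverse of :func:`to_activation_range`; round-trips exactly for k=1."""
    if act.plain_sigmoid:
        return np.asarray(h, dtype=float)
    return np.asarray(h, dtype=float) / act.k + 0.5


# ---------------------------------------------------------------------------
# CAE parameters
# ---------------------------------------------------------------------------


@dataclass
class CAEParams:
    """Weights and biases of one encoder/decoder pair."""

    W_enc: np.ndarray  # (hidden, visible)
    b_enc: np.ndarray  # (hidden,)
    W_dec: np.ndarray  # (visible, hidden)
    b_dec: np.ndarray  # (visible,)
    act: ActivationConfig = field(default_factory=ActivationConfig)

    def __post_init__(self) -> None:
        self.W_enc = np.asarray(self.W_enc, dtype=float)
        self.b_enc = np.asarray(self.b_enc, dtype=float)
        self.W_dec = np.asarray(self.W_dec, dtype=float)
        self.b_dec = np.asarray(self.b_dec, dtype=float)
        h, v = self.W_enc.shape
        if self.b_enc.shape != (h,):
            raise ValueError("b_enc shape mismatch")
        if self.W_dec.shape != (v, h):
            raise ValueError("W_dec shape mismatch")
        if self.b_dec.shape != (v,):
            raise ValueError("b_dec shape mismatch")
        for arr in (self.W_enc, self.b_enc, self.W_dec, self.b_dec):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite parameter entries")

    @property
    def visible(self) -> int:
        return self.W_enc.shape[1]

    @property
    def hidden(self) -> int:
        return self.W_enc.shape[0]

    def arrays(self) -> list[np.ndarray]:
        """Live views of all parameter arrays, in a fixed order."""
        return [self.W_enc, self.b_enc, self.W_dec, self.b_dec]

    def copy(self) -> "CAEParams":
        return CAEParams(self.W_enc.copy(), self.b_enc.copy(),
                         self.W_dec.copy(), self.b_dec.copy(),
                         copy.copy(self.act))


@dataclass
class CAEGrads:
    """Gradient structure matching :class:`CAEParams`."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def arrays(self) -> list[np.ndarray]:
        return [self.W_enc, self.b_enc, self.W_dec, self.b_dec]


def init_params(visible: int, hidden: int,
                act: ActivationConfig | None = None,
                seed: int | np.random.Generator = 0) -> CAEParams:
    """Seeded Glorot-style uniform initialisation.

    Weights uniform on ``(-r, r)`` with ``r = sqrt(6 / (visible + hidden))``;
    biases zero.
    """
    if visible < 1 or hidden < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = np.sqrt(6.0 / (visible + hidden))
    return CAEParams(
        W_enc=rng.uniform(-r, r, size=(hidden, visible)),
        b_enc=np.zeros(hidden),
        W_dec=rng.uniform(-r, r, size=(visible, hidden)),
        b_dec=np.zeros(visible),
        act=act if act is not None else ActivationConfig(),
    )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def noisy_preactivation(W: np.ndarray, x: np.ndarray, b: np.ndarray,
                        act: ActivationConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """``W @ x + b`` plus per-unit ``sigma * N(0,1)`` noise while training.

    ``x`` may be a vector ``(v,)`` or batch ``(m, v)``; noise is drawn
    i.i.d. per unit (and per sample in the batch case).
    """
    W = np.asarray(W, dtype=float)
    x = np.asarray(x, dtype=float)
    b = np.asarray(b, dtype=float)
    if x.ndim == 1:
        if W.shape[1] != x.shape[0]:
            raise ValueError(f"shape mismatch: W {W.shape} @ x {x.shape}")
        # same BLAS path as the batch case, so results agree bitwise
        pre = (x[None, :] @ W.T)[0] + b
    else:
        if W.shape[1] != x.shape[1]:
            raise ValueError(f"shape mismatch: W {W.shape} @ X {x.shape}")
        pre = x @ W.T + b
    if act.train_mode and act.sigma > 0:
        if rng is None:
            raise ValueError("rng required when stochastic units are active")
        pre = pre + act.sigma * rng.standard_normal(pre.shape)
    return pre


def encode(x: np.ndarray, p: CAEParams,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Hidden representation of `x` (vector or batch)."""
    return improved_sigmoid(noisy_preactivation(p.W_enc, x, p.b_enc, p.act, rng), p.act)


def decode(h: np.ndarray, p: CAEParams,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Reconstruction from a hidden representation."""
    return improved_sigmoid(noisy_preactivation(p.W_dec, h, p.b_dec, p.act, rng), p.act)


def reconstruct(x: np.ndarray, p: CAEParams,
                rng: np.random.Generator | None = None) -> np.ndarray:
    return decode(encode(x, p, rng), p, rng)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def sample_loss(x: np.ndarray, y: np.ndarray, p: CAEParams) -> float:
    """Deterministic single-sample squared error ``0.5 * ||h(x) - y||^2``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape != (p.visible,):
        raise ValueError("x and y must both match the visible layer size")
    det = CAEParams(p.W_enc, p.b_enc, p.W_dec, p.b_dec, p.act.eval_mode())
    r = reconstruct(x, det)
    return 0.5 * float(np.sum((r - y) ** 2))


def total_loss(X: np.ndarray, Y: np.ndarray, p: CAEParams, lc: LossConfig) -> float:
    """Mean per-sample squared-error loss plus the weight-decay term.

    Decay is ``lambda/2 * sum(W^2)`` over both weight matrices; biases are
    excluded.  Noise is off (monitoring/evaluation semantics).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if X.shape != Y.shape:
        raise ValueError("X and Y shapes differ")
    det = CAEParams(p.W_enc, p.b_enc, p.W_dec, p.b_dec, p.act.eval_mode())
    R = reconstruct(X, det)
    data = 0.5 * float(np.mean(np.sum((R - Y) ** 2, axis=1)))
    decay = 0.5 * lc.lambda_decay * (float(np.sum(p.W_enc ** 2)) +
                                     float(np.sum(p.W_dec ** 2)))
    return data + decay


def gradients(X: np.ndarray, Y: np.ndarray, p: CAEParams, lc: LossConfig,
              rng: np.random.Generator | None = None) -> CAEGrads:
    """Exact analytic gradient of :func:`total_loss` w.r.t. all parameters.

    When stochastic units are active, the noise drawn in the forward pass is
    reused in the backward pass (the draw is treated as a constant; no
    gradient flows through sigma).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = X.shape[0]
    if m == 0:
        raise ValueError("empty batch")
    if X.shape != Y.shape or X.shape[1] != p.visible:
        raise ValueError("batch shape mismatch")
    act = p.act
    A1 = noisy_preactivation(p.W_enc, X, p.b_enc, act, rng)
    H = improved_sigmoid(A1, act)
    A2 = noisy_preactivation(p.W_dec, H, p.b_dec, act, rng)
    R = improved_sigmoid(A2, act)

    d2 = (R - Y) * activation_deriv(A2, act) / m          # (m, v)
    dW_dec = d2.T @ H + lc.lambda_decay * p.W_dec
    db_dec = d2.sum(axis=0)
    d1 = (d2 @ p.W_dec) * activation_deriv(A1, act)       # (m, h)
    dW_enc = d1.T @ X + lc.lambda_decay * p.W_enc
    db_enc = d1.sum(axis=0)
    return CAEGrads(dW_enc, db_enc, dW_dec, db_dec)


# ---------------------------------------------------------------------------
# trainable wrapper
# ---------------------------------------------------------------------------


class CAE:
    """One continuous autoencoder bundled with its loss config.

    Satisfies the trainable protocol used by :mod:`caehar.optim`:
    ``parameters()``, ``sample_gradients(x, y, rng)`` and
    ``batch_loss(X, Y)``.
    """

    def __init__(self, params: CAEParams, loss_cfg: LossConfig | None = None):
        self.params = params
        self.loss_cfg = loss_cfg if loss_cfg is not None else LossConfig()

    @classmethod
    def new(cls, visible: int, hidden: int,
            act: ActivationConfig | None = None,
            loss_cfg: LossConfig | None = None,
            seed: int | np.random.Generator = 0) -> "CAE":
        return cls(init_params(visible, hidden, act, seed), loss_cfg)

    def parameters(self) -> list[np.ndarray]:
        return self.params.arrays()

    def sample_gradients(self, x: np.ndarray, y: np.ndarray,
                         rng: np.random.Generator) -> list[np.ndarray]:
        g = gradients(x[None, :], y[None, :], self.params, self.loss_cfg, rng)
        return g.arrays()

    def batch_loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        return total_loss(X, Y, self.params, self.loss_cfg)

    def clone(self) -> "CAE":
        return CAE(self.params.copy(), copy.copy(self.loss_cfg))
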