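"""Per-sample SGD training loops with an optional early-break rule (FSGD).

The fast variant monitors an epoch-level loss and stops once it has stayed
at or below a threshold ``epsilon`` for ``K`` consecutive epochs.  Both
loops share one code path, so with identical seeds their parameter
trajectories are bit-identical up to the break epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FSGDConfig",
    "TrainHistory",
    "EarlyBreak",
    "sgd_step",
    "sgd_train",
    "fsgd_train",
    "suggest_epsilon",
]


@dataclass
class FSGDConfig:
    """Hyperparameters of the (F)SGD loop.

    ``monitor`` selects what the break rule watches: ``"train"`` uses the
    epoch-mean loss over the full training set, ``"holdout"`` reserves
    ``holdout_fraction`` of the data for monitoring only.  ``consecutive``
    resets the below-threshold counter whenever an epoch exceeds epsilon;
    set it False for a cumulative count.
    """

    n: int = 1000
    alpha: float = 0.1
    epsilon: float = 0.003
    K: int = 100
    seed: int = 0
    monitor: str = "train"
    holdout_fraction: float = 0.1
    consecutive: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (1 <= self.K <= self.n):
            raise ValueError("K must satisfy 1 <= K <= n")
        if self.monitor not in ("train", "holdout"):
            raise ValueError(f"unknown monitor mode {self.monitor!r}")


@dataclass
class TrainHistory:
    """Per-epoch loss trace of one training run."""

    losses: list[float] = field(default_factory=list)
    break_epoch: int = 0
    broke_early: bool = False
    seed: int = 0

    def to_table(self, path) -> None:
        """Write a two-column (epoch, loss) tab-delimited file."""
        with open(path, "w") as fh:
            fh.write("epoch\tloss\n")
            for i, loss in enumerate(self.losses, start=1):
                fh.write(f"{i}\t{loss!r}\n")

    @classmethod
    def from_table(cls, path) -> "TrainHistory":
        losses = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                losses.append(float(line.split("\t")[1]))
        return cls(losses=losses, break_epoch=len(losses))


class EarlyBreak:
    """Counter for the break rule: stop after K epochs with loss <= epsilon.

    With ``consecutive=True`` the counter resets on any epoch above the
    threshold.
    """

    def __init__(self, epsilon: float, K: int, consecutive: bool = True):
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        self.epsilon = epsilon
        self.K = K
        self.consecutive = consecutive
        self.count = 0

    def update(self, loss: float) -> bool:
        """Record one epoch loss; return True when the loop should break."""
        if loss <= self.epsilon:
            self.count += 1
        elif self.consecutive:
            self.count = 0
        return self.count >= self.K


def sgd_step(theta, grad, alpha: float):
    """One gradient step ``theta - alpha * grad``.

    Accepts a single array or a sequence of arrays; shapes must match
    elementwise.
    """
    if isinstance(theta, np.ndarray) or np.isscalar(theta):
        theta = np.asarray(theta, dtype=float)
        grad = np.asarray(grad, dtype=float)
        if theta.shape != grad.shape:
            raise ValueError("theta and grad shapes differ")
        return theta - alpha * grad
    if len(theta) != len(grad):
        raise ValueError("theta and grad structures differ")
    return [sgd_step(t, g, alpha) for t, g in zip(theta, grad)]


def _run(model, X, Y, cfg: FSGDConfig, early_break: bool):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    m = X.shape[0]
    if m == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)

    if cfg.monitor == "holdout":
        n_hold = max(1, int(round(cfg.holdout_fraction * m)))
        if n_hold >= m:
            raise ValueError("holdout fraction leaves no training data")
        perm = rng.permutation(m)
        hold, train = perm[:n_hold], perm[n_hold:]
        X_tr, Y_tr = X[train], Y[train]
        X_mon, Y_mon = X[hold], Y[hold]
    else:
        X_tr, Y_tr = X, Y
        X_mon, Y_mon = X, Y

    brk = EarlyBreak(cfg.epsilon, cfg.K, cfg.consecutive) if early_break else None
    params = model.parameters()
    history = TrainHistory(seed=cfg.seed)
    m_tr = X_tr.shape[0]
    for epoch in range(1, cfg.n + 1):
        order = rng.permutation(m_tr)
        for i in order:
            grads = model.sample_gradients(X_tr[i], Y_tr[i], rng)
            for p, g in zip(params, grads):
                p -= cfg.alpha * g
        loss = model.batch_loss(X_mon, Y_mon)
        history.losses.append(loss)
        history.break_epoch = epoch
        if brk is not None and brk.update(loss):
            history.broke_early = True
            break
    return model, history


def sgd_train(model, X, Y=None, cfg: FSGDConfig = FSGDConfig()):
    """Plain per-sample SGD for ``cfg.n`` epochs; epsilon is ignored.

    Each epoch visits the samples once in a seeded random order, applying
    one single-sample gradient step per visit; the history records the
    deterministic epoch-mean loss.
    """
    return _run(model, X, Y, cfg, early_break=False)


def fsgd_train(model, X, Y=None, cfg: FSGDConfig = FSGDConfig()):
    """SGD with the early break: stop after K epochs at or below epsilon."""
    if cfg.epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return _run(model, X, Y, cfg, early_break=True)


def suggest_epsilon(model, X, Y=None, cfg: FSGDConfig = FSGDConfig(),
                    subsample: float = 0.25, tail_fraction: float = 0.25,
                    quantile: float = 0.5) -> float:
    """Propose a break threshold by the a-posteriori method.

    Trains a deep copy of `model` on a seeded subsample with plain SGD and
    returns the given quantile of the late-epoch (last ``tail_fraction``)
    losses.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    m = X.shape[0]
    n_sub = max(1, int(round(subsample * m)))
    idx = rng.permutation(m)[:n_sub]
    probe = copy.deepcopy(model)
    _, hist = sgd_train(probe, X[idx], Y[idx], cfg)
    tail = max(1, int(round(tail_fraction * len(hist.losses))))
    return float(np.quantile(hist.losses[-tail:], quantile))
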