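"""K-fold evaluation: fold planning, confusion matrices, channel subsetting
and the end-to-end train/evaluate driver (TFFE -> PCA -> DBN)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dbn as dbn_mod
from . import pca_reduce, tffe

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "PipelineConfig",
    "EvalResult",
    "kfold_split",
    "holdout_split",
    "confusion",
    "channel_subset",
    "train_eval",
]


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    K: int
    assignment: np.ndarray  # fold index per segment
    seed: int
    stratified: bool

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.K)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def kfold_split(labels, K: int, seed: int = 0, stratified: bool = True,
                subjects=None) -> FoldPlan:
    """Seeded K-fold assignment with fold sizes differing by at most one.

    Stratification deals each class group (sub-grouped by subject when
    given) round-robin into the folds; the dealing counter runs across
    groups so global balance holds too.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        assignment[perm] = np.arange(n) % K
        return FoldPlan(K, assignment, seed, stratified)

    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer samples than K={K}")
    if subjects is not None:
        subjects = np.asarray(subjects)
        group_keys = [(lab, subj) for lab, subj in zip(labels, subjects)]
    else:
        group_keys = list(labels)
    order = {}
    for i, key in enumerate(group_keys):
        order.setdefault(key, []).append(i)
    counter = 0
    for key in sorted(order):
        idx = np.asarray(order[key])
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            assignment[i] = counter % K
            counter += 1
    return FoldPlan(K, assignment, seed, stratified)


def holdout_split(labels, subjects, n_test_per_group: int = 10, seed: int = 0):
    """Train/test split holding out the last ``n_test_per_group`` segments of
    every (label, subject) pair (after a seeded shuffle within the pair)."""
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for i, key in enumerate(zip(labels, subjects)):
        groups.setdefault(key, []).append(i)
    train, test = [], []
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        if len(idx) <= n_test_per_group:
            raise ValueError(f"group {key} too small to hold out {n_test_per_group}")
        idx = idx[rng.permutation(len(idx))]
        test.extend(idx[:n_test_per_group])
        train.extend(idx[n_test_per_group:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="true\\pred")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if not np.array_equal(self.classes, other.classes):
            raise ValueError("class sets differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion(true_labels, pred_labels, classes=None) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays differ in length")
    if classes is None:
        classes = np.unique(true_labels)
    classes = np.asarray(classes)
    index = {lab: i for i, lab in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


# ---------------------------------------------------------------------------
# channel subsetting
# ---------------------------------------------------------------------------


def channel_subset(seg: tffe.SensorSegment, sensors=None, positions=None
                   ) -> tffe.SensorSegment:
    """Restrict a segment to the chosen sensor types and/or body positions."""
    sensors = set(sensors) if sensors is not None else set(tffe.SENSORS)
    positions = set(positions) if positions is not None else set(tffe.POSITIONS)
    keep = [i for i, m in enumerate(seg.channel_meta)
            if m.sensor in sensors and m.position in positions]
    if not keep:
        raise ValueError("channel selection is empty")
    meta = tuple(seg.channel_meta[i] for i in keep)
    return tffe.SensorSegment(seg.data[:, keep], meta,
                              label=seg.label, subject=seg.subject)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of one TFFE -> PCA -> DBN evaluation run."""

    dbn: dbn_mod.DBNSpec = field(default_factory=dbn_mod.DBNSpec)
    n_keep: int = 3
    pca_mode: str = "pooled"
    sensors: tuple | None = None
    positions: tuple | None = None


@dataclass
class EvalResult:
    mean_accuracy: float
    fold_accuracies: list[float]
    fold_matrices: list[ConfusionMatrix]
    aggregate: ConfusionMatrix
    plan: FoldPlan


def train_eval(segments, labels, cfg: PipelineConfig | None = None,
               K: int = 6, seed: int = 0, classifier_factory=None) -> EvalResult:
    """K-fold evaluation of the full pipeline.

    Features are extracted once; per fold, the PCA basis and the classifier
    are fit on training data only.  ``classifier_factory(train_X, train_y,
    fold_seed) -> predict_fn`` can replace the DBN (used for stub oracles in
    tests).
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    labels = np.asarray(labels)
    if cfg.sensors is not None or cfg.positions is not None:
        segments = [channel_subset(s, cfg.sensors, cfg.positions)
                    for s in segments]
    subjects = np.asarray([s.subject for s in segments])
    if np.any(subjects == None):  # noqa: E711 - object array sentinel
        subjects = None
    features = tffe.extract_matrix(segments)
    plan = kfold_split(labels, K, seed, stratified=True, subjects=subjects)
    classes = np.unique(labels)
    seeds = np.random.SeedSequence(seed).generate_state(K)

    fold_accs: list[float] = []
    fold_cms: list[ConfusionMatrix] = []
    for fold in range(K):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        basis = pca_reduce.fit_pca(features[tr], n_keep=cfg.n_keep,
                                   mode=cfg.pca_mode,
                                   n_channels=segments[0].n_channels)
        Xtr = pca_reduce.project(features[tr], basis)
        Xte = pca_reduce.project(features[te], basis)
        fold_seed = int(seeds[fold])
        if classifier_factory is not None:
            predict_fn = classifier_factory(Xtr, labels[tr], fold_seed)
            pred = np.asarray(predict_fn(Xte))
        else:
            stack = dbn_mod.pretrain_stack(Xtr, cfg.dbn, seed=fold_seed)
            model = dbn_mod.finetune(stack, Xtr, labels[tr], cfg.dbn,
                                     seed=fold_seed)
            pred, _ = dbn_mod.predict(model, Xte)
        cm = confusion(labels[te], pred, classes=classes)
        fold_cms.append(cm)
        fold_accs.append(cm.accuracy)
    aggregate = fold_cms[0]
    for cm in fold_cms[1:]:
        aggregate = aggregate + cm
    return EvalResult(mean_accuracy=aggregate.accuracy,
                      fold_accuracies=fold_accs, fold_matrices=fold_cms,
                      aggregate=aggregate, plan=plan)
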