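"""Training loop, loss, cross-validation splits and segmentation metrics.

Training follows the protocol the architecture was designed around: Adam
at learning rate 0.01, dropout 0.1, 200 epochs, batch size one graph
(each cortical graph is ~10k nodes, so one subject is one batch and batch
normalization runs over the N nodes), cross-entropy plus an L2 penalty on
the weight matrices, and subject-level 5-fold cross-validation.

Evaluation reports the per-region Dice coefficient
``2|G_c ∩ P_c| / (|G_c| + |P_c|)`` and overall vertex accuracy
``|G ∩ P| / |G|``; both live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import (ModelConfig, ModelParams, _model_forward_t, init_params,
                    predict_labels, tensors_for)
from .synthetic import Subject

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "standardize_features",
    "loss",
    "kfold_split",
    "train",
    "cross_validate",
    "dice",
    "mean_dice",
    "accuracy",
    "evaluate",
]

IGNORE_INDEX = -1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 1          # one graph per optimizer step
    dropout: float = 0.1
    weight_decay: float = 5e-4   # L2 coefficient; never printed, standard default
    folds: int = 5
    seed: int = 0
    ignore_index: int = IGNORE_INDEX

    def __post_init__(self):
        if self.learning_rate < 0 or self.epochs < 1 or self.folds < 2:
            raise ValueError("bad training configuration")
        if self.batch_size != 1:
            raise ValueError("training operates on one graph per step")


# ---------------------------------------------------------------------------
# features & loss
# ---------------------------------------------------------------------------

def standardize_features(x: np.ndarray) -> np.ndarray:
    """Per-subject, per-channel standardization to mean 0 / sd 1 over the
    N vertices; constant channels map to all zeros."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _l2_term(tensors: dict, params: ModelParams, lam: float):
    term = None
    for name, _ in params.weight_matrices():
        sq = ad.sum_squares(tensors[name])
        term = sq if term is None else term + sq
    return lam * term


def loss(z: np.ndarray, labels: np.ndarray, params: ModelParams | None = None,
         weight_decay: float = 0.0, ignore_index: int = IGNORE_INDEX) -> float:
    """Masked mean cross-entropy on probabilities plus λ·Σ‖W‖².

    The mean runs over non-ignored vertices; the L2 term covers every
    weight matrix (batch-norm affine parameters are excluded).  The
    training loop uses the taped twin of this function.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    zdata = np.asarray(z, dtype=np.float64)
    if zdata.shape[0] != len(labels):
        raise ValueError("prediction/label length mismatch")
    mask = labels != ignore_index
    if np.any((labels[mask] < 0) | (labels[mask] >= zdata.shape[1])):
        raise ValueError("label out of range")
    total = ad.cross_entropy_probs(ad.as_tensor(zdata), labels, mask)
    if weight_decay > 0 and params is not None:
        tensors = {name: Tensor(arr) for name, arr in params.trainable()}
        total = total + _l2_term(tensors, params, weight_decay)
    return float(total)


def _loss_t(zt: Tensor, labels: np.ndarray, tensors: dict, params: ModelParams,
            weight_decay: float, ignore_index: int) -> Tensor:
    mask = labels != ignore_index
    total = ad.cross_entropy_probs(zt, labels, mask)
    if weight_decay > 0:
        total = total + _l2_term(tensors, params, weight_decay)
    return total


# ---------------------------------------------------------------------------
# cross-validation & training
# ---------------------------------------------------------------------------

def kfold_split(subject_ids, folds: int = 5, seed: int = 0):
    """Seeded subject-level k-fold: disjoint test sets covering all ids,
    sizes differing by at most one."""
    ids = list(subject_ids)
    if len(ids) < folds:
        raise ValueError("fewer subjects than folds")
    order = np.random.default_rng(seed).permutation(len(ids))
    chunks = np.array_split(order, folds)
    splits = []
    for chunk in chunks:
        test = [ids[i] for i in chunk]
        train_ids = [ids[i] for i in order if i not in set(chunk)]
        splits.append((train_ids, test))
    return splits


class _Adam:
    def __init__(self, arrays: dict, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, arr in self.arrays.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            arr -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(dataset: list[Subject], model_config: ModelConfig,
          train_config: TrainConfig,
          params: ModelParams | None = None,
          log=None) -> tuple[ModelParams, list[float]]:
    """Train on a list of subjects; returns (params, per-epoch mean loss).

    Features are standardized per subject; one Adam step per subject per
    epoch, subject order reshuffled each epoch with a seeded generator.
    """
    if not dataset:
        raise ValueError("empty training set")
    cfg = model_config
    if cfg.dropout != train_config.dropout:
        cfg = ModelConfig(**{**cfg.__dict__, "dropout": train_config.dropout})
    params = params or init_params(cfg, train_config.seed)
    feats = [standardize_features(s.features) for s in dataset]
    rng = np.random.default_rng(train_config.seed + 1)
    arrays = dict(params.trainable())
    opt = _Adam(arrays, train_config.learning_rate)
    history: list[float] = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for si in order:
            subj = dataset[si]
            tensors = tensors_for(params, trainable=True)
            zt = _model_forward_t(subj.graph, feats[si], tensors, params,
                                  training=True, rng=rng)
            lt = _loss_t(zt, subj.labels, tensors, params,
                         train_config.weight_decay, train_config.ignore_index)
            if not np.isfinite(lt.data):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch}, subject {subj.id}")
            if train_config.learning_rate > 0:
                lt.backward()
                opt.step({k: tensors[k].grad for k in arrays})
            losses.append(float(lt))
        history.append(float(np.mean(losses)))
        if log is not None:
            log(epoch, history[-1])
    return params, history


def cross_validate(dataset: list[Subject], model_config: ModelConfig,
                   train_config: TrainConfig, log=None):
    """Full k-fold protocol; returns (per-fold (params, report), pooled report)."""
    by_id = {s.id: s for s in dataset}
    splits = kfold_split([s.id for s in dataset], train_config.folds,
                         train_config.seed)
    folds = []
    for train_ids, test_ids in splits:
        params, _ = train([by_id[i] for i in train_ids], model_config,
                          train_config, log=log)
        report = evaluate(params, [by_id[i] for i in test_ids],
                          ignore_index=train_config.ignore_index)
        folds.append((params, report))
    pooled = _merge_reports([r for _, r in folds])
    return folds, pooled


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def dice(g: np.ndarray, p: np.ndarray, cls: int,
         ignore_index: int = IGNORE_INDEX) -> float:
    """Per-class Dice 2|G_c ∩ P_c| / (|G_c| + |P_c|) over labeled vertices."""
    g, p = _masked(g, p, ignore_index)
    gc, pc = g == cls, p == cls
    denom = gc.sum() + pc.sum()
    if denom == 0:
        raise ValueError(f"class {cls} absent from both label vectors")
    return float(2.0 * np.sum(gc & pc) / denom)


def mean_dice(g: np.ndarray, p: np.ndarray,
              ignore_index: int = IGNORE_INDEX) -> float:
    """Macro average over the classes present in the ground truth."""
    g, p = _masked(g, p, ignore_index)
    classes = np.unique(g)
    return float(np.mean([dice(g, p, int(c)) for c in classes]))


def accuracy(g: np.ndarray, p: np.ndarray,
             ignore_index: int = IGNORE_INDEX) -> float:
    g, p = _masked(g, p, ignore_index)
    return float(np.mean(g == p))


def _masked(g, p, ignore_index):
    g = np.asarray(g, dtype=np.int64).ravel()
    p = np.asarray(p, dtype=np.int64).ravel()
    if len(g) != len(p):
        raise ValueError("label vectors differ in length")
    mask = g != ignore_index
    if not mask.any():
        raise ValueError("no labeled vertices")
    return g[mask], p[mask]


@dataclass
class MetricsReport:
    per_class_dice: dict
    mean_dice: float
    accuracy: float
    per_subject_accuracy: list = field(default_factory=list)
    n_vertices: int = 0
    # micro-pooled per-class counts, kept so fold reports can be merged
    counts: dict = field(default_factory=dict)  # cls -> [|G_c|, |P_c|, |G∩P|]

    def to_table(self) -> str:
        lines = ["class\tdice"]
        for cls in sorted(self.per_class_dice):
            lines.append(f"{cls}\t{self.per_class_dice[cls]:.6f}")
        lines += ["", f"mean_dice\t{self.mean_dice:.6f}",
                  f"accuracy\t{self.accuracy:.6f}",
                  f"n_vertices\t{self.n_vertices}"]
        return "\n".join(lines) + "\n"


def _report_from_counts(counts: dict, correct: int, total: int,
                        per_subject) -> MetricsReport:
    per_class = {}
    for cls, (ng, np_, inter) in sorted(counts.items()):
        if ng + np_ > 0 and ng > 0:  # classes never in G are excluded
            per_class[cls] = 2.0 * inter / (ng + np_)
    return MetricsReport(per_class, float(np.mean(list(per_class.values()))),
                         correct / total, per_subject, total, counts)


def evaluate(params: ModelParams, subjects: list[Subject],
             ignore_index: int = IGNORE_INDEX,
             predictions: list[np.ndarray] | None = None) -> MetricsReport:
    """Micro-pool per-class vertex counts across subjects, then Dice per
    class and a macro mean; accuracy is vertex-pooled (per-subject values
    also recorded)."""
    from .model import model_forward  # local import to avoid cycle at import time
    counts: dict = {}
    correct = total = 0
    per_subject = []
    for i, s in enumerate(subjects):
        if predictions is not None:
            pred = np.asarray(predictions[i], dtype=np.int64)
        else:
            z = model_forward(s.graph, standardize_features(s.features), params,
                              training=False)
            pred = predict_labels(z)
        g, p = _masked(s.labels, pred, ignore_index)
        for cls in np.unique(np.concatenate([g, p])):
            c = counts.setdefault(int(cls), [0, 0, 0])
            c[0] += int(np.sum(g == cls))
            c[1] += int(np.sum(p == cls))
            c[2] += int(np.sum((g == cls) & (p == cls)))
        per_subject.append(float(np.mean(g == p)))
        correct += int(np.sum(g == p))
        total += len(g)
    if total == 0:
        raise ValueError("no labeled vertices")
    return _report_from_counts(counts, correct, total, per_subject)


def _merge_reports(reports: list[MetricsReport]) -> MetricsReport:
    counts: dict = {}
    correct = total = 0
    per_subject = []
    for r in reports:
        for cls, c in r.counts.items():
            acc = counts.setdefault(cls, [0, 0, 0])
            for k in range(3):
                acc[k] += c[k]
        correct += round(r.accuracy * r.n_vertices)
        total += r.n_vertices
        per_subject += r.per_subject_accuracy
    return _report_from_counts(counts, correct, total, per_subject)
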