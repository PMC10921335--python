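"""Convolutional risk-factor comment classifier (TextCNN).

Each comment is represented as a ``max_len x d`` matrix of its token
embeddings (tail-truncated, zero-padded, OOV tokens mapped to a zero
row).  Kernels of several widths slide over token positions spanning the
full embedding width, pass through ReLU, and are globally max-pooled; the
concatenated pooled features feed an affine layer and a 2-class softmax.
Embedding rows are frozen: the classifier is a pure consumer of the
trained vectors.  Implemented directly on numpy with an Adam optimizer;
gradients are analytic and the forward pass is exercised against
hand-computed examples in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .embedding import EmbeddingModel
from .preprocess import Comment

__all__ = [
    "ClassifierConfig",
    "LabeledDataset",
    "MetricsReport",
    "CNNParams",
    "vectorize",
    "forward",
    "train_classifier",
    "evaluate",
    "cross_validate",
    "predict_corpus",
    "predict_proba",
]


@dataclass(frozen=True)
class ClassifierConfig:
    max_len: int = 64
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_size: int = 64
    dropout: float = 0.5
    epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 32
    rng_seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if max(self.kernel_sizes) > self.max_len:
            raise ValueError("kernel sizes must not exceed max_len")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 <= self.decision_threshold <= 1):
            raise ValueError("decision_threshold must be in [0, 1]")


@dataclass
class LabeledDataset:
    comments: list[Comment]

    def __post_init__(self):
        bad = [c.comment_id for c in self.comments if c.label not in (0, 1)]
        if bad:
            raise ValueError(f"unlabeled items in labeled dataset: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.comments)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.comments], dtype=int)

    def split(self, test_fraction: float = 0.1, seed: int = 0
              ) -> tuple["LabeledDataset", "LabeledDataset"]:
        """Stratified train/test split (default 90/10)."""
        rng = np.random.default_rng(seed)
        y = self.labels
        train_idx, test_idx = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_test = int(round(len(idx) * test_fraction))
            test_idx.extend(idx[:n_test])
            train_idx.extend(idx[n_test:])
        return (LabeledDataset([self.comments[i] for i in sorted(train_idx)]),
                LabeledDataset([self.comments[i] for i in sorted(test_idx)]))


@dataclass
class MetricsReport:
    """Confusion counts with the standard derived metrics.

    The derived values are recomputed from the counts on every access so
    the identities accuracy=(TP+TN)/N, precision=TP/(TP+FP),
    recall=TP/(TP+FN), F1=harmonic mean hold by construction.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / n if n else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_json(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


@dataclass
class CNNParams:
    """kernels[ks] has shape (ks*d, F); affine W: (sum F, 2), b: (2,)."""

    kernels: dict[int, np.ndarray]
    biases: dict[int, np.ndarray]
    w_affine: np.ndarray
    b_affine: np.ndarray
    config: ClassifierConfig
    loss_log: list[float] = field(default_factory=list)
    # input standardization: embedding norms depend on how long the vectors
    # were trained, so the trainer fixes 1/mean-row-norm from its training
    # set and every forward pass applies it
    input_scale: float = 1.0

    @classmethod
    def initialize(cls, d: int, cfg: ClassifierConfig,
                   rng: np.random.Generator) -> "CNNParams":
        kernels, biases = {}, {}
        for ks in cfg.kernel_sizes:
            fan_in = ks * d
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
            kernels[ks] = rng.normal(0.0, scale, (fan_in, cfg.filters_per_size))
            biases[ks] = np.zeros(cfg.filters_per_size)
        n_feat = len(cfg.kernel_sizes) * cfg.filters_per_size
        w_affine = rng.normal(0.0, np.sqrt(1.0 / n_feat), (n_feat, 2))
        return cls(kernels=kernels, biases=biases, w_affine=w_affine,
                   b_affine=np.zeros(2), config=cfg)

    def flat(self) -> list[np.ndarray]:
        out = []
        for ks in self.config.kernel_sizes:
            out += [self.kernels[ks], self.biases[ks]]
        return out + [self.w_affine, self.b_affine]


def vectorize(comment: Comment, model: EmbeddingModel,
              cfg: ClassifierConfig) -> np.ndarray:
    """max_len x d matrix: row i = embedding of token i; zero pad/OOV."""
    if model.w_in is None:
        raise ValueError("untrained embedding model")
    d = model.dimension
    mat = np.zeros((cfg.max_len, d))
    for i, tok in enumerate(comment.tokens[: cfg.max_len]):
        idx = model.vocab.index.get(tok)
        if idx is not None:
            mat[i] = model.w_in[idx]
    return mat


def _im2col(X: np.ndarray, ks: int) -> np.ndarray:
    """(B, L, d) -> (B, L-ks+1, ks*d) sliding windows over positions."""
    B, L, d = X.shape
    n_pos = L - ks + 1
    s0, s1, s2 = X.strides
    windows = np.lib.stride_tricks.as_strided(
        X, shape=(B, n_pos, ks, d), strides=(s0, s1, s1, s2))
    return windows.reshape(B, n_pos, ks * d)


def _forward_batch(X: np.ndarray, params: CNNParams,
                   dropout_mask: np.ndarray | None = None):
    """Returns (probs, cache) for a (B, L, d) batch."""
    cfg = params.config
    if params.input_scale != 1.0:
        X = X * params.input_scale
    pooled_parts, cache = [], {}
    for ks in cfg.kernel_sizes:
        cols = _im2col(X, ks)                       # B x P x ks*d
        act = cols @ params.kernels[ks] + params.biases[ks]  # B x P x F
        relu = np.maximum(act, 0.0)
        argmax = relu.argmax(axis=1)                # B x F
        pooled = np.take_along_axis(relu, argmax[:, None, :], axis=1)[:, 0, :]
        pooled_parts.append(pooled)
        cache[ks] = (cols, act, argmax)
    feat = np.concatenate(pooled_parts, axis=1)     # B x sumF
    if dropout_mask is not None:
        feat = feat * dropout_mask
    logits = feat @ params.w_affine + params.b_affine
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    cache["feat"] = feat
    cache["probs"] = probs
    return probs, cache


def forward(matrix: np.ndarray, params: CNNParams) -> float:
    """P(label = 1) for a single max_len x d comment matrix."""
    cfg = params.config
    if matrix.shape[0] != cfg.max_len:
        raise ValueError(
            f"expected {cfg.max_len} rows, got {matrix.shape[0]}")
    probs, _ = _forward_batch(matrix[None], params)
    return float(probs[0, 1])


def _backward_batch(X, y, params: CNNParams, cache, dropout_mask):
    """Cross-entropy gradients for all parameters; mean over the batch."""
    cfg = params.config
    B = X.shape[0]
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {}
    grads["w_affine"] = cache["feat"].T @ dlogits
    grads["b_affine"] = dlogits.sum(axis=0)
    dfeat = dlogits @ params.w_affine.T
    if dropout_mask is not None:
        dfeat = dfeat * dropout_mask
    offset = 0
    for ks in cfg.kernel_sizes:
        F = cfg.filters_per_size
        dpooled = dfeat[:, offset:offset + F]       # B x F
        offset += F
        cols, act, argmax = cache[ks]
        dact = np.zeros_like(act)                   # B x P x F
        b_idx = np.repeat(np.arange(B), F)
        f_idx = np.tile(np.arange(F), B)
        p_idx = argmax.ravel()
        vals = (dpooled * (act[b_idx, p_idx, f_idx].reshape(B, F) > 0)).ravel()
        np.add.at(dact, (b_idx, p_idx, f_idx), vals)
        grads[("kernel", ks)] = np.einsum("bpc,bpf->cf", cols, dact)
        grads[("bias", ks)] = dact.sum(axis=(0, 1))
    return grads


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[object, np.ndarray], grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _param_dict(params: CNNParams) -> dict:
    d = {"w_affine": params.w_affine, "b_affine": params.b_affine}
    for ks in params.config.kernel_sizes:
        d[("kernel", ks)] = params.kernels[ks]
        d[("bias", ks)] = params.biases[ks]
    return d


def train_classifier(data: LabeledDataset, model: EmbeddingModel,
                     cfg: ClassifierConfig) -> CNNParams:
    """Train the CNN on frozen embeddings; deterministic given rng_seed."""
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.rng_seed)
    X = np.stack([vectorize(c, model, cfg) for c in data.comments])
    params = CNNParams.initialize(model.dimension, cfg, rng)
    norms = np.linalg.norm(X, axis=2)
    mean_norm = norms[norms > 0].mean() if np.any(norms > 0) else 1.0
    params.input_scale = float(1.0 / mean_norm)
    pdict = _param_dict(params)
    opt = _Adam({k: v.shape for k, v in pdict.items()}, cfg.learning_rate)
    n = len(data)
    n_feat = len(cfg.kernel_sizes) * cfg.filters_per_size
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            mask = None
            if cfg.dropout > 0:
                keep = (rng.random((len(idx), n_feat)) >= cfg.dropout)
                mask = keep / (1.0 - cfg.dropout)  # inverted dropout
            probs, cache = _forward_batch(Xb, params, mask)
            epoch_loss += float(
                -np.log(probs[np.arange(len(idx)), yb] + 1e-300).mean())
            nb += 1
            grads = _backward_batch(Xb, yb, params, cache, mask)
            opt.step(pdict, grads)
        params.loss_log.append(epoch_loss / max(nb, 1))
    return params


def predict_proba(params: CNNParams, comments: Sequence[Comment],
                  model: EmbeddingModel, cfg: ClassifierConfig) -> np.ndarray:
    """P(label=1) for each comment, batched, no dropout."""
    if not comments:
        return np.empty(0)
    out = np.empty(len(comments))
    for start in range(0, len(comments), 256):
        chunk = comments[start:start + 256]
        X = np.stack([vectorize(c, model, cfg) for c in chunk])
        probs, _ = _forward_batch(X, params)
        out[start:start + len(chunk)] = probs[:, 1]
    return out


def evaluate(params: CNNParams, test: LabeledDataset,
             model: EmbeddingModel, cfg: ClassifierConfig) -> MetricsReport:
    """Confusion counts from thresholded probabilities on a test set."""
    if not len(test):
        raise ValueError("empty test set")
    p = predict_proba(params, test.comments, model, cfg)
    pred = (p >= cfg.decision_threshold).astype(int)
    y = test.labels
    return MetricsReport(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )


def _mean_report(reports: Sequence[MetricsReport]) -> dict:
    return {
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "precision": float(np.mean([r.precision for r in reports])),
        "recall": float(np.mean([r.recall for r in reports])),
        "f1": float(np.mean([r.f1 for r in reports])),
    }


def cross_validate(data: LabeledDataset, model: EmbeddingModel,
                   cfg: ClassifierConfig, folds: int = 10
                   ) -> tuple[list[MetricsReport], dict]:
    """Stratified k-fold CV: each fold validates once; seeded shuffling."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = data.labels
    for cls in (0, 1):
        if (y == cls).sum() < folds:
            raise ValueError(f"fewer than {folds} items of class {cls}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=cfg.rng_seed)
    reports = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        train_ds = LabeledDataset([data.comments[i] for i in train_idx])
        val_ds = LabeledDataset([data.comments[i] for i in val_idx])
        params = train_classifier(train_ds, model, cfg)
        reports.append(evaluate(params, val_ds, model, cfg))
    return reports, _mean_report(reports)


def predict_corpus(params: CNNParams, comments: Sequence[Comment],
                   model: EmbeddingModel, cfg: ClassifierConfig
                   ) -> list[tuple[Comment, float]]:
    """Comments whose P(risk factor) clears the decision threshold."""
    p = predict_proba(params, comments, model, cfg)
    return [(c, float(pi)) for c, pi in zip(comments, p)
            if pi >= cfg.decision_threshold]
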