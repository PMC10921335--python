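"""Topic-enhanced Skip-gram word embeddings (TopicS).

Training couples two prediction tasks on each center word of a sliding
window: (1) the classic Skip-gram task of predicting the context words
within +/- c positions, and (2) predicting the topic of the center word
whenever the center word appears in the topic dictionary.  The combined
objective is

    L_s = L_cont + lambda * L_topic

where L_cont is the mean negative log-likelihood of context words given
the center word's input vector (full softmax when ``negative_samples`` is
0, the negative-sampling objective otherwise), and L_topic is the mean,
over dictionary-labeled centers, of the dictionary-weight-scaled negative
log-likelihood of the true topic under a softmax over a separate
topic-output matrix.  With lambda = 0 the model reduces exactly to plain
Skip-gram; that reduction is asserted numerically against an independently
written baseline in the test suite.

All parameters live in three dense matrices: the input matrix W_in
(|V| x d, whose rows are the exported word vectors), the context-output
matrix W_out (|V| x d), and the topic-output matrix W_topic (K x d).
Because inputs are one-hot, "multiplying by the input matrix" is a row
lookup, and all gradients are analytic and exercised against central
finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .preprocess import Comment, Vocabulary, build_vocab
from .topicdict import TopicDictionary

__all__ = [
    "TrainingConfig",
    "TrainingExample",
    "EmbeddingModel",
    "LossBreakdown",
    "generate_training_windows",
    "loss",
    "gradients",
    "apply_gradients",
    "train",
    "most_similar",
    "save_word2vec",
    "load_word2vec",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for TopicS training.

    window : half-width c of the sliding context window.
    dimension : embedding size d.
    lam : weight balancing L_cont and L_topic; 0 disables the topic task.
    negative_samples : k noise words per positive pair; 0 = full softmax.
    """

    window: int = 5
    dimension: int = 100
    lam: float = 1.0
    learning_rate: float = 0.025
    epochs: int = 5
    negative_samples: int = 0
    rng_seed: int = 0
    min_count: int = 1
    linear_decay: bool = True
    background_class: bool = False  # extra topic class for undictionaried words

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.negative_samples < 0:
            raise ValueError("negative_samples must be >= 0")


@dataclass
class TrainingExample:
    """One window: a center word index, its context indices, its topic label.

    ``topic`` is None when the center word is absent from the topic
    dictionary (no supervision is fabricated for unlabeled words unless the
    background-class variant is switched on).  ``topic_weight`` carries the
    dictionary weight that scales this word's topic-loss term.
    """

    center: int
    contexts: list[int]
    topic: int | None = None
    topic_weight: float = 1.0


@dataclass
class EmbeddingModel:
    vocab: Vocabulary
    w_in: np.ndarray      # |V| x d — the word vectors
    w_out: np.ndarray     # |V| x d — context-output parameters
    w_topic: np.ndarray   # K x d   — topic-output parameters
    config: TrainingConfig
    topic_ids: list[str] = field(default_factory=list)
    loss_curve: list[dict] = field(default_factory=list)

    @property
    def dimension(self) -> int:
        return self.w_in.shape[1]

    def vector(self, word: str) -> np.ndarray:
        return self.w_in[self.vocab.index[word]]

    @classmethod
    def initialize(cls, vocab: Vocabulary, cfg: TrainingConfig,
                   topic_ids: Sequence[str] = ()) -> "EmbeddingModel":
        """Uniform [-0.5/d, 0.5/d] input matrix, zero output matrices; seeded."""
        rng = np.random.default_rng(cfg.rng_seed)
        V, d = len(vocab), cfg.dimension
        n_topics = len(topic_ids) + (1 if cfg.background_class else 0)
        w_in = (rng.random((V, d)) - 0.5) / d
        return cls(
            vocab=vocab,
            w_in=w_in,
            w_out=np.zeros((V, d)),
            w_topic=np.zeros((max(n_topics, 1), d)),
            config=cfg,
            topic_ids=list(topic_ids),
        )


@dataclass
class LossBreakdown:
    l_cont: float
    l_topic: float
    lam: float
    n_pairs: int
    n_topic_terms: int

    @property
    def l_s(self) -> float:
        return self.l_cont + self.lam * self.l_topic


def generate_training_windows(
    tokens: Sequence[int],
    cfg: TrainingConfig,
    topic_of: dict[int, tuple[int, float]] | None = None,
) -> Iterator[TrainingExample]:
    """Slide a +/-window over an indexed token sequence.

    One example per position; contexts truncated at sequence ends.
    ``topic_of`` maps word index -> (topic index, dictionary weight).
    """
    topic_of = topic_of or {}
    c = cfg.window
    T = len(tokens)
    for i in range(T):
        contexts = [tokens[j] for j in range(max(0, i - c), min(T, i + c + 1))
                    if j != i]
        topic, weight = topic_of.get(tokens[i], (None, 1.0))
        yield TrainingExample(center=tokens[i], contexts=contexts,
                              topic=topic, topic_weight=weight)


def _batch_arrays(batch: Sequence[TrainingExample]):
    """Flatten a batch into (center, context) pair arrays and topic arrays."""
    pc, px = [], []
    tc, tt, tw = [], [], []
    for ex in batch:
        for ctx in ex.contexts:
            pc.append(ex.center)
            px.append(ctx)
        if ex.topic is not None:
            tc.append(ex.center)
            tt.append(ex.topic)
            tw.append(ex.topic_weight)
    return (np.asarray(pc, dtype=np.intp), np.asarray(px, dtype=np.intp),
            np.asarray(tc, dtype=np.intp), np.asarray(tt, dtype=np.intp),
            np.asarray(tw, dtype=float))


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _noise_distribution(vocab: Vocabulary) -> np.ndarray:
    """Unigram^0.75 noise distribution over vocabulary indices."""
    counts = np.empty(len(vocab))
    for w, i in vocab.index.items():
        counts[i] = vocab.counts[w]
    p = counts ** 0.75
    return p / p.sum()


def _loss_and_grads(
    batch: Sequence[TrainingExample],
    model: EmbeddingModel,
    lam: float,
    negatives: np.ndarray | None = None,
):
    """Shared forward/backward pass.

    Returns (LossBreakdown, dW_in, dW_out, dW_topic).  ``negatives`` is a
    (n_pairs, k) index array for the negative-sampling objective; None means
    full softmax.
    """
    pc, px, tc, tt, tw = _batch_arrays(batch)
    n_pairs = len(pc)
    n_topic = len(tc)
    if n_pairs == 0:
        # distinguish from the benign no-topic-labels case (L_topic = 0)
        raise ValueError("no context pairs in batch")

    d_in = np.zeros_like(model.w_in)
    d_out = np.zeros_like(model.w_out)
    d_topic = np.zeros_like(model.w_topic)
    l_cont = 0.0
    l_topic = 0.0

    if n_pairs:
        vc = model.w_in[pc]                       # n_pairs x d
        if negatives is None:
            scores = vc @ model.w_out.T           # n_pairs x V
            p = _softmax(scores)
            l_cont = float(-np.log(p[np.arange(n_pairs), px] + 1e-300).mean())
            p[np.arange(n_pairs), px] -= 1.0      # dL/dscores, per pair
            p /= n_pairs
            d_out += p.T @ vc
            g_vc = p @ model.w_out
        else:
            pos = _sigmoid(np.einsum("nd,nd->n", vc, model.w_out[px]))
            sneg = np.einsum("nd,nkd->nk", vc, model.w_out[negatives])
            neg = _sigmoid(-sneg)
            l_cont = float(-(np.log(pos + 1e-300)
                             + np.log(neg + 1e-300).sum(axis=1)).mean())
            g_pos = (pos - 1.0) / n_pairs                       # n_pairs
            g_neg = _sigmoid(sneg) / n_pairs                    # n_pairs x k
            np.add.at(d_out, px, g_pos[:, None] * vc)
            np.add.at(d_out, negatives,
                      g_neg[:, :, None] * vc[:, None, :])
            g_vc = (g_pos[:, None] * model.w_out[px]
                    + np.einsum("nk,nkd->nd", g_neg, model.w_out[negatives]))
        np.add.at(d_in, pc, g_vc)

    if n_topic and lam > 0.0 and model.w_topic.shape[0] > 0:
        vt = model.w_in[tc]
        q = _softmax(vt @ model.w_topic.T)        # n_topic x K
        l_topic = float((tw * -np.log(q[np.arange(n_topic), tt] + 1e-300)).mean())
        q[np.arange(n_topic), tt] -= 1.0
        q *= (lam * tw / n_topic)[:, None]
        d_topic += q.T @ vt
        np.add.at(d_in, tc, q @ model.w_topic)
    elif n_topic:
        # lambda = 0: report L_topic for logging but contribute no gradient
        vt = model.w_in[tc]
        if model.w_topic.shape[0] > 0:
            q = _softmax(vt @ model.w_topic.T)
            l_topic = float((tw * -np.log(q[np.arange(n_topic), tt] + 1e-300)).mean())

    breakdown = LossBreakdown(l_cont=l_cont, l_topic=l_topic, lam=lam,
                              n_pairs=n_pairs, n_topic_terms=n_topic)
    return breakdown, d_in, d_out, d_topic


def loss(batch: Sequence[TrainingExample], model: EmbeddingModel,
         negatives: np.ndarray | None = None) -> LossBreakdown:
    """L_s = L_cont + lambda * L_topic on a batch (no parameter update)."""
    breakdown, *_ = _loss_and_grads(batch, model, model.config.lam, negatives)
    return breakdown


def gradients(batch: Sequence[TrainingExample], model: EmbeddingModel,
              negatives: np.ndarray | None = None):
    """Analytic gradients of L_s w.r.t. (w_in, w_out, w_topic)."""
    _, d_in, d_out, d_topic = _loss_and_grads(
        batch, model, model.config.lam, negatives)
    return d_in, d_out, d_topic


def apply_gradients(model: EmbeddingModel, grads, lr: float) -> None:
    d_in, d_out, d_topic = grads
    model.w_in -= lr * d_in
    model.w_out -= lr * d_out
    model.w_topic -= lr * d_topic


def train(
    corpus: Sequence[Comment] | Sequence[Sequence[str]],
    topic_dict: TopicDictionary | None,
    cfg: TrainingConfig,
    vocab: Vocabulary | None = None,
) -> EmbeddingModel:
    """Train TopicS on tokenized comments.

    Each comment is one batch: its windows are enumerated, the batch-mean
    L_s is computed and one SGD step taken.  Deterministic given
    ``cfg.rng_seed``.  Per-epoch mean losses are recorded on
    ``model.loss_curve``.
    """
    token_lists = [c.tokens if isinstance(c, Comment) else list(c)
                   for c in corpus]
    token_lists = [t for t in token_lists if t]
    if not token_lists:
        raise ValueError("empty corpus")
    if vocab is None:
        vocab = build_vocab(
            [Comment(comment_id=str(i), raw_text="", tokens=t)
             for i, t in enumerate(token_lists)],
            min_count=cfg.min_count)
    if cfg.negative_samples >= len(vocab):
        raise ValueError("vocabulary smaller than negative_samples + 1")

    topic_ids = topic_dict.topic_ids() if topic_dict else []
    model = EmbeddingModel.initialize(vocab, cfg, topic_ids)
    topic_index = {t: i for i, t in enumerate(topic_ids)}
    topic_of: dict[int, tuple[int, float]] = {}
    if topic_dict is not None:
        for word, idx in vocab.index.items():
            hit = topic_dict.lookup(word)
            if hit is not None:
                topic_of[idx] = (topic_index[hit[0]], hit[1])
        if cfg.background_class:
            bg = len(topic_ids)
            for word, idx in vocab.index.items():
                if idx not in topic_of:
                    topic_of[idx] = (bg, 1.0)

    indexed = [[vocab.index[t] for t in toks if t in vocab.index]
               for toks in token_lists]
    indexed = [t for t in indexed if t]

    rng = np.random.default_rng(cfg.rng_seed)
    noise = _noise_distribution(vocab) if cfg.negative_samples else None
    total_steps = max(cfg.epochs * len(indexed), 1)
    step = 0
    for epoch in range(cfg.epochs):
        sums = {"l_cont": 0.0, "l_topic": 0.0, "l_s": 0.0}
        n_batches = 0
        for tokens in indexed:
            batch = list(generate_training_windows(tokens, cfg, topic_of))
            n_pairs = sum(len(ex.contexts) for ex in batch)
            if n_pairs == 0:
                continue  # single-token comment: no window supervision
            negatives = None
            if cfg.negative_samples and n_pairs:
                negatives = rng.choice(
                    len(vocab), size=(n_pairs, cfg.negative_samples), p=noise)
            lr = cfg.learning_rate
            if cfg.linear_decay:
                lr = cfg.learning_rate * max(1e-4, 1.0 - step / total_steps)
            breakdown, d_in, d_out, d_topic = _loss_and_grads(
                batch, model, cfg.lam, negatives)
            apply_gradients(model, (d_in, d_out, d_topic), lr)
            sums["l_cont"] += breakdown.l_cont
            sums["l_topic"] += breakdown.l_topic
            n_batches += 1
            step += 1
        if n_batches:
            l_cont = sums["l_cont"] / n_batches
            l_topic = sums["l_topic"] / n_batches
            # l_s derived from the logged means so the decomposition
            # identity holds exactly in floating point
            model.loss_curve.append({"epoch": epoch, "l_cont": l_cont,
                                     "l_topic": l_topic,
                                     "l_s": l_cont + cfg.lam * l_topic})
    return model


def most_similar(word: str, model: EmbeddingModel, topn: int = 10
                 ) -> list[tuple[str, float]]:
    """Top-n neighbors by cosine over input-matrix rows; query excluded.

    Ties broken by vocabulary index (stable argsort on negated cosines).
    """
    if word not in model.vocab.index:
        raise KeyError(f"out-of-vocabulary query: {word!r}")
    qi = model.vocab.index[word]
    W = model.w_in
    norms = np.linalg.norm(W, axis=1)
    norms[norms == 0] = 1.0
    sims = (W @ W[qi]) / (norms * max(norms[qi], 1e-300))
    sims[qi] = -np.inf
    order = np.argsort(-sims, kind="stable")[:topn]
    words = model.vocab.words
    return [(words[i], float(sims[i])) for i in order if np.isfinite(sims[i])]


# ---------------------------------------------------------------------------
# word2vec text format

def save_word2vec(model: EmbeddingModel, path: str | Path) -> None:
    """Header "V d", then one "word v1 ... vd" line per word, in index order."""
    words = model.vocab.words
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {model.dimension}\n")
        for i, w in enumerate(words):
            vec = " ".join(repr(float(x)) for x in model.w_in[i])
            fh.write(f"{w} {vec}\n")


def load_word2vec(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        V, d = int(header[0]), int(header[1])
        words, rows = [], np.empty((V, d))
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            words.append(parts[0])
            rows[i] = [float(x) for x in parts[1:]]
    return words, rows
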