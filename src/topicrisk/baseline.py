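"""Plain Skip-gram baseline, written independently of the TopicS code.

This is a deliberately simple, loop-based full-softmax Skip-gram trainer.
It shares the initialization scheme, batching convention (one comment =
one batch, batch-mean loss) and learning-rate schedule with the TopicS
trainer so that TopicS with lambda = 0 must reproduce its parameter
trajectory exactly — the reduction check in the test suite compares the
two step for step.  It shares none of the forward/backward code.
"""

from __future__ import annotations

import numpy as np

from .preprocess import Comment, Vocabulary, build_vocab
from .embedding import TrainingConfig

__all__ = ["SkipgramBaseline", "train_skipgram"]


class SkipgramBaseline:
    """Minimal full-softmax Skip-gram with per-batch SGD."""

    def __init__(self, vocab: Vocabulary, cfg: TrainingConfig):
        rng = np.random.default_rng(cfg.rng_seed)
        V, d = len(vocab), cfg.dimension
        self.vocab = vocab
        self.cfg = cfg
        self.w_in = (rng.random((V, d)) - 0.5) / d
        self.w_out = np.zeros((V, d))
        self.loss_curve: list[float] = []

    def _step(self, tokens: list[int], lr: float) -> float:
        c = self.cfg.window
        T = len(tokens)
        pairs = []
        for i in range(T):
            for j in range(max(0, i - c), min(T, i + c + 1)):
                if j != i:
                    pairs.append((tokens[i], tokens[j]))
        if not pairs:
            return 0.0
        g_in = np.zeros_like(self.w_in)
        g_out = np.zeros_like(self.w_out)
        total = 0.0
        n = len(pairs)
        for center, context in pairs:
            v = self.w_in[center]
            s = self.w_out @ v
            s = s - s.max()
            p = np.exp(s)
            p /= p.sum()
            total += -np.log(p[context] + 1e-300)
            delta = p.copy()
            delta[context] -= 1.0
            g_out += np.outer(delta, v) / n
            g_in[center] += (delta @ self.w_out) / n
        self.w_in -= lr * g_in
        self.w_out -= lr * g_out
        return total / n

    def train(self, token_lists: list[list[int]]) -> "SkipgramBaseline":
        cfg = self.cfg
        total_steps = max(cfg.epochs * len(token_lists), 1)
        step = 0
        for _epoch in range(cfg.epochs):
            epoch_loss, nb = 0.0, 0
            for tokens in token_lists:
                if len(tokens) < 2:
                    continue
                lr = cfg.learning_rate
                if cfg.linear_decay:
                    lr = cfg.learning_rate * max(1e-4, 1.0 - step / total_steps)
                epoch_loss += self._step(tokens, lr)
                nb += 1
                step += 1
            if nb:
                self.loss_curve.append(epoch_loss / nb)
        return self


def train_skipgram(corpus, cfg: TrainingConfig,
                   vocab: Vocabulary | None = None) -> SkipgramBaseline:
    """Train the baseline on tokenized comments (same I/O as TopicS train)."""
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
    indexed = [[vocab.index[t] for t in toks if t in vocab.index]
               for toks in token_lists]
    indexed = [t for t in indexed if t]
    model = SkipgramBaseline(vocab, cfg)
    return model.train(indexed)
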