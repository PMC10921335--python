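"""Synthetic short-comment corpora with planted topic structure.

The generator emulates the statistical shape of a crawled comment corpus:
short documents, a heavy-tailed (Zipf) background vocabulary, a labeled
subset with near-balanced classes, and a fraction of ultrashort noise
comments.  Risk comments are assigned one of ``n_topics`` planted topics
and draw each token from that topic's vocabulary with probability
``topic_purity`` (background otherwise); non-risk comments draw from the
background only.  The planted dictionary, per-comment topic and label are
returned as ground truth so every downstream module can be scored against
a known answer.  Vocabulary is ASCII pseudo-words (``topic3_w07``,
``bg_w0042``) so the whitespace tokenizer suffices.

Everything is driven by one integer seed through numpy's PCG64 generator;
identical configs and seeds give identical corpora on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .classifier import LabeledDataset
from .preprocess import Comment
from .topicdict import TopicDictionary, assign_weights

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "generate_labeled_set",
    "generate_seed_phrases",
    "embedding_benchmark_config",
    "labeled_set_config",
    "clustering_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Planted-structure corpus parameters.

    topic_purity is the probability that a token of a risk comment comes
    from its topic's vocabulary; it must exceed the chance rate of any
    single background word for the structure to be learnable.
    """

    n_topics: int = 2
    words_per_topic: int = 50
    background_vocab_size: int = 200
    n_comments: int = 2000
    min_length: int = 6
    max_length: int = 14
    risk_fraction: float = 0.5
    topic_purity: float = 0.9
    ultrashort_fraction: float = 0.05
    zipf_exponent: float = 1.1
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("risk_fraction", "topic_purity", "ultrashort_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.n_topics < 1 or self.words_per_topic < 1:
            raise ValueError("need at least one topic and one word per topic")


def embedding_benchmark_config(seed: int = 0) -> GeneratorConfig:
    """Default planted-topic corpus: 2 topics x 50 words, 2000 comments."""
    return GeneratorConfig(rng_seed=seed)


def labeled_set_config(seed: int = 0) -> GeneratorConfig:
    """Default labeled set for classifier benchmarks: n = 400, balanced."""
    return GeneratorConfig(n_comments=400, ultrashort_fraction=0.0,
                           rng_seed=seed)


def clustering_config(seed: int = 0) -> GeneratorConfig:
    """Five well-separated planted clusters, 500 risk documents."""
    return GeneratorConfig(n_topics=5, words_per_topic=30, n_comments=500,
                           risk_fraction=1.0, topic_purity=0.95,
                           ultrashort_fraction=0.0, rng_seed=seed)


def _topic_vocab(cfg: GeneratorConfig) -> list[list[str]]:
    return [[f"topic{t}_w{i:02d}" for i in range(cfg.words_per_topic)]
            for t in range(cfg.n_topics)]


def _background_vocab(cfg: GeneratorConfig) -> list[str]:
    return [f"bg_w{i:04d}" for i in range(cfg.background_vocab_size)]


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return p / p.sum()


def true_dictionary(cfg: GeneratorConfig) -> TopicDictionary:
    """The planted dictionary: every topic word, risk-weighted."""
    d = TopicDictionary()
    for t, words in enumerate(_topic_vocab(cfg)):
        assign_weights(words, f"topic{t}", risk=True, topic_dict=d)
    return d


def generate_corpus(cfg: GeneratorConfig
                    ) -> tuple[list[Comment], dict, TopicDictionary]:
    """Generate comments plus ground truth.

    Returns (comments, ground_truth, true_dictionary) where ground_truth
    maps comment_id -> {"label": 0/1, "topic": int or None}.  Label and
    ultrashort allocations are exact (round(n * fraction) items), not
    binomial, so configured counts are hit exactly.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    topics = _topic_vocab(cfg)
    background = _background_vocab(cfg)
    bg_probs = _zipf_probs(len(background), cfg.zipf_exponent)

    n = cfg.n_comments
    n_risk = int(round(n * cfg.risk_fraction))
    n_ultra = int(round(n * cfg.ultrashort_fraction))
    labels = np.array([1] * n_risk + [0] * (n - n_risk))
    rng.shuffle(labels)
    ultra = np.zeros(n, dtype=bool)
    ultra[rng.choice(n, size=n_ultra, replace=False)] = True

    comments, truth = [], {}
    for i in range(n):
        label = int(labels[i])
        topic = int(rng.integers(cfg.n_topics)) if label == 1 else None
        if ultra[i]:
            length = int(rng.integers(1, 3))  # 1-2 tokens
        else:
            length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        tokens = []
        for _ in range(length):
            if label == 1 and rng.random() < cfg.topic_purity:
                tokens.append(topics[topic][int(rng.integers(cfg.words_per_topic))])
            else:
                tokens.append(background[int(rng.choice(len(background), p=bg_probs))])
        cid = f"c{i:05d}"
        comments.append(Comment(
            comment_id=cid, raw_text=" ".join(tokens), tokens=tokens,
            label=label))
        truth[cid] = {"label": label, "topic": topic,
                      "ultrashort": bool(ultra[i])}
    return comments, truth, true_dictionary(cfg)


def generate_labeled_set(cfg: GeneratorConfig
                         ) -> tuple[LabeledDataset, dict]:
    """A labeled dataset shaped like a manual annotation round.

    Ultrashort noise is excluded (annotation happens after filtering).
    """
    cfg = replace(cfg, ultrashort_fraction=0.0)
    comments, truth, _ = generate_corpus(cfg)
    return LabeledDataset(comments), truth


def generate_seed_phrases(cfg: GeneratorConfig, k_per_topic: int,
                          seed: int | None = None) -> list[list[str]]:
    """k true topic words per topic, drawn without replacement.

    Stands in for manually extracted risk-factor phrase spans; output is a
    phrase collection (each phrase a token list) whose tokens are all in
    the planted dictionary.
    """
    if k_per_topic > cfg.words_per_topic:
        raise ValueError("k_per_topic exceeds words_per_topic")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    phrases = []
    for words in _topic_vocab(cfg):
        chosen = rng.choice(len(words), size=k_per_topic, replace=False)
        phrases.append([words[int(i)] for i in sorted(chosen)])
    return phrases
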