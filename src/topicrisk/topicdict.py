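"""Semi-automated topic dictionary: seeds plus embedding-neighbor expansion.

The risk-factor topic dictionary starts from seed words taken out of
manually extracted risk-factor phrases.  Each expansion iteration queries
the trained embedding for every current member's nearest neighbors by
cosine similarity and adds them to the set; the loop stops after a
configured number of iterations or at a fixed point.  Risk-factor words
carry a larger weight than other topics' words; that weight later scales
the word's topic-loss term during embedding training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .embedding import EmbeddingModel

__all__ = [
    "TopicDictionary",
    "ExpansionConfig",
    "seeds_from_phrases",
    "expand_topic",
    "assign_weights",
]

DEFAULT_WEIGHT = 1.0
RISK_WEIGHT = 2.0


@dataclass
class TopicDictionary:
    """topic_id -> {word -> weight}; a word belongs to at most one topic."""

    topics: dict[str, dict[str, float]] = field(default_factory=dict)
    default_weight: float = DEFAULT_WEIGHT
    risk_weight: float = RISK_WEIGHT

    def topic_ids(self) -> list[str]:
        return list(self.topics)

    def lookup(self, word: str) -> tuple[str, float] | None:
        topic = self._owner.get(word)
        if topic is None:
            return None
        return topic, self.topics[topic][word]

    def __contains__(self, word: str) -> bool:
        return word in self._owner

    def __len__(self) -> int:
        return len(self._owner)

    @property
    def _owner(self) -> dict[str, str]:
        # word -> owning topic, rebuilt lazily and cached on content change
        cached = getattr(self, "_owner_cache", None)
        size = sum(len(ws) for ws in self.topics.values())
        if cached is None or cached[1] != size:
            owner = {}
            for t, ws in self.topics.items():
                for w in ws:
                    owner[w] = t
            object.__setattr__(self, "_owner_cache", (owner, size))
            return owner
        return cached[0]

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.topics, fh, ensure_ascii=False, indent=1,
                      sort_keys=True)

    @classmethod
    def load_json(cls, path: str | Path) -> "TopicDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls(topics=json.load(fh))


@dataclass(frozen=True)
class ExpansionConfig:
    """topn neighbors per member, number of loop iterations, optional
    similarity floor below which neighbors are not adopted."""

    topn: int = 5
    iterations: int = 3
    similarity_floor: float = -1.0

    def __post_init__(self):
        if self.topn < 0 or self.iterations < 0:
            raise ValueError("topn and iterations must be >= 0")


def seeds_from_phrases(phrases: Iterable[Sequence[str]]) -> set[str]:
    """Deduplicated union of tokens from risk-factor phrase spans."""
    seeds: set[str] = set()
    for phrase in phrases:
        seeds.update(phrase)
    if not seeds:
        warnings.warn("empty phrase collection: seed set is empty")
    return seeds


def expand_topic(seeds: set[str], model: "EmbeddingModel",
                 cfg: ExpansionConfig) -> set[str]:
    """Grow the seed set by repeated nearest-neighbor adoption.

    Each iteration adds, for every current member, its ``topn`` nearest
    vocabulary neighbors by cosine (above ``similarity_floor``).  Stops
    after ``cfg.iterations`` or when an iteration adds nothing.
    Deterministic given model and config; out-of-vocabulary seeds are
    skipped with a warning.
    """
    from .embedding import most_similar

    if model.w_in is None or not len(model.vocab):
        raise ValueError("untrained model")
    in_vocab = {s for s in seeds if s in model.vocab.index}
    oov = seeds - in_vocab
    if oov:
        warnings.warn(f"skipping {len(oov)} out-of-vocabulary seeds")
    current = set(in_vocab)
    for _ in range(cfg.iterations):
        added: set[str] = set()
        for word in sorted(current):
            for neighbor, sim in most_similar(word, model, cfg.topn):
                if sim >= cfg.similarity_floor and neighbor not in current:
                    added.add(neighbor)
        if not added:
            break
        current |= added
    return current


def assign_weights(words: Iterable[str], topic_id: str, risk: bool,
                   topic_dict: TopicDictionary) -> TopicDictionary:
    """Map words to a topic with the risk or default weight.

    A word already owned by another topic is moved only if the new weight
    is strictly larger (higher-weight-wins, first-come on ties).
    """
    if topic_dict.default_weight <= 0 or topic_dict.risk_weight <= 0:
        raise ValueError("configured weights must be positive")
    weight = topic_dict.risk_weight if risk else topic_dict.default_weight
    words = list(words)
    if not words:
        raise ValueError("assign_weights requires a non-empty word set")
    bucket = topic_dict.topics.setdefault(topic_id, {})
    for word in words:
        hit = topic_dict.lookup(word)
        if hit is not None:
            old_topic, old_weight = hit
            if weight <= old_weight:
                continue
            del topic_dict.topics[old_topic][word]
        bucket[word] = weight
        object.__setattr__(topic_dict, "_owner_cache", None)
    return topic_dict
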