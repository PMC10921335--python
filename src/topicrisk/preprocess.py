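"""Comment cleaning, segmentation, stopword removal and vocabulary building.

The pipeline consumes short social-media comments (one per line or one per
TSV row).  Cleaning strips URLs, e-mail addresses and symbol noise;
segmentation turns the cleaned string into tokens while protecting
multi-word domain terms from a user dictionary; ultrashort comments
("Thank you!"-class noise) are filtered by a token-count threshold before
any downstream modelling.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Comment",
    "Vocabulary",
    "CleaningConfig",
    "clean_text",
    "segment",
    "remove_stopwords",
    "filter_ultrashort",
    "build_vocab",
    "coverage_fraction",
    "run_preprocess",
    "read_comments",
    "write_comments_jsonl",
    "read_comments_jsonl",
    "read_wordlist",
]

UNLABELED = -1

URL_PATTERN = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
EMAIL_PATTERN = re.compile(r"\S+@\S+\.\S+")
# Conservative whitelist: keep letters, digits, CJK, whitespace and basic
# punctuation; everything else (emoticons, dingbats, control chars) is noise.
_SYMBOL_PATTERN = re.compile(r"[^\w\s一-鿿.,;:!?'\"()\-]", re.UNICODE)
_SPACE_PATTERN = re.compile(r"\s+")


@dataclass
class Comment:
    """One social-media text item.

    ``raw_text`` is never mutated by the pipeline; cleaning writes
    ``clean_text`` and segmentation writes ``tokens``.
    """

    comment_id: str
    raw_text: str
    post_id: str | None = None
    clean_text: str | None = None
    tokens: list[str] = field(default_factory=list)
    label: int = UNLABELED

    def is_labeled(self) -> bool:
        return self.label in (0, 1)

    def to_json(self) -> dict:
        d = {
            "comment_id": self.comment_id,
            "raw_text": self.raw_text,
            "tokens": self.tokens,
        }
        if self.post_id is not None:
            d["post_id"] = self.post_id
        if self.clean_text is not None:
            d["clean_text"] = self.clean_text
        if self.is_labeled():
            d["label"] = self.label
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Comment":
        return cls(
            comment_id=str(d["comment_id"]),
            raw_text=d.get("raw_text", ""),
            post_id=d.get("post_id"),
            clean_text=d.get("clean_text"),
            tokens=list(d.get("tokens", [])),
            label=int(d.get("label", UNLABELED)),
        )


@dataclass(frozen=True)
class CleaningConfig:
    """Knobs for the cleaning/segmentation/filtering stage.

    ``min_tokens`` is the ultrashort-filter threshold: comments with fewer
    tokens are dropped as noise.  Default 3 drops one/two-word replies while
    keeping short symptom reports.
    """

    stopwords: frozenset[str] = frozenset()
    user_dictionary: tuple[str, ...] = ()
    min_tokens: int = 3
    url_pattern: re.Pattern = URL_PATTERN
    email_pattern: re.Pattern = EMAIL_PATTERN
    symbol_pattern: re.Pattern = _SYMBOL_PATTERN

    def __post_init__(self):
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        for term in self.user_dictionary:
            if not term:
                raise ValueError("user_dictionary entries must be non-empty")


@dataclass
class Vocabulary:
    """Word <-> contiguous integer index plus corpus counts.

    Ranking is by count descending, ties broken lexicographically, so index
    order is deterministic and ``coverage_fraction`` is reproducible.
    """

    index: dict[str, int]
    counts: dict[str, int]
    total_token_count: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    @property
    def words(self) -> list[str]:
        out = [""] * len(self.index)
        for w, i in self.index.items():
            out[i] = w
        return out

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tindex\tcount\n")
            for w in self.words:
                fh.write(f"{w}\t{self.index[w]}\t{self.counts[w]}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        counts: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                w, i, c = line.rstrip("\n").split("\t")
                index[w] = int(i)
                counts[w] = int(c)
        return cls(index=index, counts=counts,
                   total_token_count=sum(counts.values()))


def clean_text(raw: str, cfg: CleaningConfig | None = None) -> str:
    """Strip URLs, e-mail addresses and symbol noise; collapse whitespace.

    Idempotent: applying twice gives the same string.
    """
    cfg = cfg or CleaningConfig()
    text = unicodedata.normalize("NFKC", raw)
    text = cfg.url_pattern.sub(" ", text)
    text = cfg.email_pattern.sub(" ", text)
    text = cfg.symbol_pattern.sub(" ", text)
    text = _SPACE_PATTERN.sub(" ", text).strip()
    return text


def segment(text: str, cfg: CleaningConfig | None = None) -> list[str]:
    """Tokenize cleaned text, emitting user-dictionary terms as single tokens.

    Default backend is whitespace splitting with longest-match protection of
    multi-word dictionary terms (the terms are joined before splitting and
    restored afterwards).  A dictionary-aware CJK segmenter can be plugged in
    by replacing this function in the pipeline config; the downstream modules
    only see token lists.
    """
    cfg = cfg or CleaningConfig()
    if not text:
        return []
    protected: dict[str, str] = {}
    work = text
    # longest terms first so "dust mite allergy" wins over "dust mite"
    for n, term in enumerate(sorted(cfg.user_dictionary, key=len, reverse=True)):
        if term in work:
            placeholder = f"\x00{n}\x00"
            protected[placeholder] = term
            work = work.replace(term, f" {placeholder} ")
    tokens = []
    for tok in work.split():
        tokens.append(protected.get(tok, tok))
    return tokens


def remove_stopwords(tokens: Sequence[str], cfg: CleaningConfig) -> list[str]:
    """Drop stopword occurrences, preserving order of the rest."""
    return [t for t in tokens if t not in cfg.stopwords]


def filter_ultrashort(
    comments: Sequence[Comment], cfg: CleaningConfig
) -> tuple[list[Comment], list[Comment]]:
    """Partition comments into (kept, dropped) by the min_tokens threshold."""
    kept = [c for c in comments if len(c.tokens) >= cfg.min_tokens]
    dropped = [c for c in comments if len(c.tokens) < cfg.min_tokens]
    return kept, dropped


def build_vocab(comments: Sequence[Comment], min_count: int = 1) -> Vocabulary:
    """Count corpus tokens and rank them (count desc, then lexicographic)."""
    counter: Counter[str] = Counter()
    for c in comments:
        counter.update(c.tokens)
    counter = Counter({w: n for w, n in counter.items() if n >= min_count})
    if not counter:
        raise ValueError("empty corpus: no trainable vocabulary")
    ranked = sorted(counter, key=lambda w: (-counter[w], w))
    return Vocabulary(
        index={w: i for i, w in enumerate(ranked)},
        counts=dict(counter),
        total_token_count=sum(counter.values()),
    )


def coverage_fraction(vocab: Vocabulary, top_k: int) -> float:
    """Fraction of corpus tokens covered by the top_k ranked words."""
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    if not vocab.index:
        raise ValueError("empty vocabulary")
    ranked = vocab.words  # already in rank order
    covered = sum(vocab.counts[w] for w in ranked[:top_k])
    return covered / vocab.total_token_count


def run_preprocess(
    comments: Iterable[Comment], cfg: CleaningConfig
) -> tuple[list[Comment], list[Comment]]:
    """Full cleaning pipeline: clean -> segment -> stopwords -> ultrashort.

    Returns (kept, dropped).  ``raw_text`` on every comment is untouched.
    """
    processed = []
    for c in comments:
        c = replace_fields(c, cfg)
        processed.append(c)
    return filter_ultrashort(processed, cfg)


def replace_fields(c: Comment, cfg: CleaningConfig) -> Comment:
    cleaned = clean_text(c.raw_text, cfg)
    tokens = remove_stopwords(segment(cleaned, cfg), cfg)
    return replace(c, clean_text=cleaned, tokens=tokens)


# ---------------------------------------------------------------------------
# I/O

def read_comments(path: str | Path) -> list[Comment]:
    """Read raw comments from plain text (one per line) or TSV/CSV.

    Delimited files must carry a header with a ``text`` column and optional
    ``post_id`` / ``comment_id`` / ``label`` columns.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        delim = "\t" if "\t" in first else ("," if path.suffix == ".csv" else None)
        if delim and "text" in first.split(delim):
            reader = csv.DictReader(fh, delimiter=delim)
            out = []
            for i, row in enumerate(reader):
                out.append(Comment(
                    comment_id=row.get("comment_id") or str(i),
                    post_id=row.get("post_id"),
                    raw_text=row["text"],
                    label=int(row["label"]) if row.get("label") not in (None, "") else UNLABELED,
                ))
            return out
        return [Comment(comment_id=str(i), raw_text=line.rstrip("\n"))
                for i, line in enumerate(fh) if line.strip()]


def write_comments_jsonl(comments: Iterable[Comment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(json.dumps(c.to_json(), ensure_ascii=False, sort_keys=True) + "\n")


def read_comments_jsonl(path: str | Path) -> list[Comment]:
    with open(path, encoding="utf-8") as fh:
        return [Comment.from_json(json.loads(line)) for line in fh if line.strip()]


def read_wordlist(path: str | Path) -> list[str]:
    """One term per line, UTF-8; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
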