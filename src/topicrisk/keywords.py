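"""Per-category keyword extraction with TextRank.

Each cluster category is treated as one document: its members' token
lists are concatenated, a word co-occurrence graph is built (an
undirected edge between two words for every token-position pair closer
than the window size, weighted by the co-occurrence count), and the
damped TextRank recursion

    S(u) = (1 - dfac) + dfac * sum_{v in N(u)} w(u,v) / deg_w(v) * S(v)

is iterated from a uniform start until the largest score change drops
below the tolerance.  Isolated words score exactly 1 - dfac.  Reported
keyword weights are each word's share of the category's total score mass,
so a top-10 listing sums to less than 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

__all__ = [
    "KeywordConfig",
    "KeywordScores",
    "build_graph",
    "textrank",
    "top_keywords",
    "wordcloud_export",
    "wordcloud_import",
]


@dataclass(frozen=True)
class KeywordConfig:
    window_size: int = 5
    damping: float = 0.85
    tol: float = 1e-6
    max_iter: int = 200
    weighted_edges: bool = True

    def __post_init__(self):
        if not (0 < self.damping < 1):
            raise ValueError("damping must be in (0, 1)")


@dataclass
class KeywordScores:
    scores: dict[str, float]
    damping: float
    iterations: int
    converged: bool


def build_graph(tokens: Sequence[str], window_size: int = 5,
                weighted: bool = True) -> nx.Graph:
    """Co-occurrence graph: edge weight = number of token-position pairs
    at distance < window_size; no self-loops; symmetric by construction."""
    g = nx.Graph()
    g.add_nodes_from(tokens)
    for i, u in enumerate(tokens):
        for j in range(i + 1, min(i + window_size, len(tokens))):
            v = tokens[j]
            if u == v:
                continue
            if g.has_edge(u, v):
                if weighted:
                    g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def textrank(graph: nx.Graph, damping: float = 0.85, tol: float = 1e-6,
             max_iter: int = 200) -> KeywordScores:
    """Damped voting iteration over the co-occurrence graph."""
    if not (0 < damping < 1):
        raise ValueError("damping must be in (0, 1)")
    nodes = sorted(graph.nodes)
    scores = {u: 1.0 for u in nodes}
    strength = {u: sum(d["weight"] for d in graph[u].values()) for u in nodes}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = {}
        for u in nodes:
            vote = sum(graph[u][v]["weight"] / strength[v] * scores[v]
                       for v in graph[u])
            new[u] = (1.0 - damping) + damping * vote
        delta = max(abs(new[u] - scores[u]) for u in nodes)
        scores = new
        if delta < tol:
            converged = True
            break
    return KeywordScores(scores=scores, damping=damping,
                         iterations=it, converged=converged)


def top_keywords(category_tokens: Sequence[str], n: int,
                 cfg: KeywordConfig | None = None
                 ) -> list[tuple[str, float]]:
    """Top-n words of a category by normalized TextRank score.

    Weights are score shares over the category's full vocabulary (they sum
    to 1 across all words, so any top-n listing sums to less than 1).
    Ties broken lexicographically.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not category_tokens:
        raise ValueError("empty category")
    cfg = cfg or KeywordConfig()
    graph = build_graph(category_tokens, cfg.window_size, cfg.weighted_edges)
    ks = textrank(graph, cfg.damping, cfg.tol, cfg.max_iter)
    total = sum(ks.scores.values())
    ranked = sorted(ks.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(w, s / total) for w, s in ranked[:n]]


def wordcloud_export(scores: dict[str, float], path: str | Path) -> None:
    """word<TAB>weight table consumable by any word-cloud renderer."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tweight\n")
        for w, s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{w}\t{s:.6f}\n")


def wordcloud_import(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            w, s = line.rstrip("\n").split("\t")
            out[w] = float(s)
    return out
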