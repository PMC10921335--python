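"""Single-pass clustering with an automatic review of singleton categories.

Documents arrive in order; each joins the existing category whose centroid
is most cosine-similar, provided that similarity clears the threshold
theta, and otherwise founds a new category.  Because an early document can
found a category whose centroid later drifts, the plain single pass is
order-sensitive and tends to strand stragglers in singleton categories.
The review pass re-scores every singleton against the non-singleton
centroids once all documents have been seen and merges those that now
clear theta; a report of category sizes, central examples and keywords is
emitted for the human review stage, and reviewer decisions (merges,
relabels) can be applied back onto the cluster set.

Documents are represented as the unweighted mean of their in-vocabulary
token embeddings; all-OOV (zero-vector) documents are quarantined and
reported separately, never clustered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingModel
from .preprocess import Comment

__all__ = [
    "DocumentVector",
    "Category",
    "ClusterSet",
    "doc_vector",
    "idf_weights",
    "single_pass",
    "review_pass",
    "review_report",
    "apply_review_decisions",
]


@dataclass
class DocumentVector:
    comment_id: str
    vector: np.ndarray
    quarantined: bool = False


@dataclass
class Category:
    category_id: int
    centroid: np.ndarray
    members: list[str] = field(default_factory=list)
    created_order: int = 0
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    categories: list[Category] = field(default_factory=list)
    theta: float = 0.5
    quarantined: list[str] = field(default_factory=list)
    review_log: list[dict] = field(default_factory=list)
    _vectors: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def assignment(self) -> dict[str, int]:
        return {m: c.category_id for c in self.categories for m in c.members}

    def singleton_ids(self) -> list[int]:
        return [c.category_id for c in self.categories if c.size == 1]

    def recompute_centroids(self) -> None:
        for c in self.categories:
            c.centroid = np.mean([self._vectors[m] for m in c.members], axis=0)

    def save_assignments_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("comment_id\tcategory_id\n")
            for c in self.categories:
                for m in c.members:
                    fh.write(f"{m}\t{c.category_id}\n")
            for m in self.quarantined:
                fh.write(f"{m}\t-1\n")


def doc_vector(comment: Comment, model: EmbeddingModel,
               token_weights: dict[str, float] | None = None
               ) -> DocumentVector:
    """Mean of in-vocabulary token vectors; zero-norm docs are quarantined.

    ``token_weights`` switches to a weighted mean (e.g. IDF weights from
    :func:`idf_weights`); the default is the unweighted mean.
    """
    rows, weights = [], []
    for t in comment.tokens:
        idx = model.vocab.index.get(t)
        if idx is None:
            continue
        rows.append(model.w_in[idx])
        weights.append(1.0 if token_weights is None
                       else token_weights.get(t, 0.0))
    if rows and sum(weights) > 0:
        vec = np.average(rows, axis=0, weights=weights)
    else:
        vec = np.zeros(model.dimension)
    return DocumentVector(comment_id=comment.comment_id, vector=vec,
                          quarantined=not np.linalg.norm(vec) > 0)


def idf_weights(comments: Sequence[Comment]) -> dict[str, float]:
    """Smoothed inverse document frequency: ln((1+N)/(1+df)) + 1."""
    n = len(comments)
    df: dict[str, int] = {}
    for c in comments:
        for t in set(c.tokens):
            df[t] = df.get(t, 0) + 1
    return {t: float(np.log((1 + n) / (1 + d)) + 1.0)
            for t, d in df.items()}


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def single_pass(docs: Sequence[DocumentVector], theta: float = 0.5
                ) -> ClusterSet:
    """One-scan incremental clustering at cosine threshold theta.

    Deterministic for a fixed document order; ties on the best cosine go
    to the earlier-created category (strict > comparison during the scan).
    """
    if not (0 < theta < 1):
        raise ValueError("theta must be in (0, 1)")
    cs = ClusterSet(theta=theta)
    for order, doc in enumerate(docs):
        if doc.quarantined:
            cs.quarantined.append(doc.comment_id)
            continue
        cs._vectors[doc.comment_id] = doc.vector
        best, best_sim = None, -np.inf
        for cat in cs.categories:
            sim = _cosine(doc.vector, cat.centroid)
            if sim > best_sim:
                best, best_sim = cat, sim
        if best is not None and best_sim >= theta:
            # incremental mean update
            n = best.size
            best.centroid = (best.centroid * n + doc.vector) / (n + 1)
            best.members.append(doc.comment_id)
        else:
            cs.categories.append(Category(
                category_id=len(cs.categories), centroid=doc.vector.copy(),
                members=[doc.comment_id], created_order=order))
    return cs


def review_pass(cs: ClusterSet) -> ClusterSet:
    """Re-traverse singleton categories once, merging into non-singletons.

    Each singleton's document is scored against every non-singleton
    centroid; if the best cosine clears theta the singleton is dissolved
    into that category and the centroid updated.  Singletons are never
    merged with each other (that would just re-run the original problem),
    and merged singletons are not revisited, so the sweep terminates and
    neither the category count nor the singleton count can increase.
    """
    singles = [c for c in cs.categories if c.size == 1]
    targets = [c for c in cs.categories if c.size > 1]
    if not singles or not targets:
        return cs
    for single in singles:
        doc_id = single.members[0]
        vec = cs._vectors[doc_id]
        best, best_sim = None, -np.inf
        for cat in targets:
            sim = _cosine(vec, cat.centroid)
            if sim > best_sim:
                best, best_sim = cat, sim
        if best is not None and best_sim >= cs.theta:
            n = best.size
            best.centroid = (best.centroid * n + vec) / (n + 1)
            best.members.append(doc_id)
            cs.categories.remove(single)
            cs.review_log.append({
                "action": "auto_merge_singleton",
                "comment_id": doc_id,
                "from_category": single.category_id,
                "into_category": best.category_id,
                "cosine": best_sim,
            })
    return cs


def review_report(cs: ClusterSet, comments: Sequence[Comment] | None = None,
                  top_examples: int = 3,
                  keywords_per_category: int = 0) -> dict:
    """Per-category summary for the manual review stage.

    Lists each category's size and its most-central member texts (highest
    cosine to the centroid).  The human decision itself is out of scope;
    its output is consumed by :func:`apply_review_decisions`.
    """
    text_of = {c.comment_id: (c.clean_text or c.raw_text)
               for c in comments or []}
    report = {"theta": cs.theta, "n_categories": len(cs.categories),
              "n_clustered": sum(c.size for c in cs.categories),
              "n_quarantined": len(cs.quarantined),
              "categories": []}
    for cat in sorted(cs.categories, key=lambda c: -c.size):
        sims = sorted(
            ((_cosine(cs._vectors[m], cat.centroid), m) for m in cat.members),
            key=lambda t: (-t[0], t[1]))
        report["categories"].append({
            "category_id": cat.category_id,
            "size": cat.size,
            "central_members": [
                {"comment_id": m, "cosine": s,
                 **({"text": text_of[m]} if m in text_of else {})}
                for s, m in sims[:top_examples]],
        })
    return report


def apply_review_decisions(cs: ClusterSet, decisions: Sequence[dict]
                           ) -> ClusterSet:
    """Apply reviewer merge/relabel decisions.

    Each decision is {"action": "merge", "source": id, "target": id} or
    {"action": "relabel", "source": id, "label": str}.  Unknown category
    ids and self-merges are errors; merges are applied in order.
    """
    for dec in decisions:
        action = dec.get("action")
        by_id = {c.category_id: c for c in cs.categories}
        if action == "merge":
            src, dst = dec["source"], dec["target"]
            if src == dst:
                raise ValueError(f"cyclic merge: {src} -> {dst}")
            if src not in by_id or dst not in by_id:
                raise KeyError(f"unknown category id in merge: {dec}")
            source, target = by_id[src], by_id[dst]
            target.members.extend(source.members)
            target.centroid = np.mean(
                [cs._vectors[m] for m in target.members], axis=0)
            cs.categories.remove(source)
            cs.review_log.append({"action": "manual_merge",
                                  "source": src, "target": dst})
        elif action == "relabel":
            if dec["source"] not in by_id:
                raise KeyError(f"unknown category id in relabel: {dec}")
            by_id[dec["source"]].label = dec["label"]
            cs.review_log.append({"action": "relabel", **dec})
        else:
            raise ValueError(f"unknown review action: {action!r}")
    return cs
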