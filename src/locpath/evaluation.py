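"""Global and path-local assessment of ranked pathway reconstructions.

Ground truth is a curated pathway's interaction set (positives) plus a
seeded random sample of interactome edges outside it (negatives, by default
50 per positive).  Assessment is twofold:

* **global** — interactions are ordered by the index of the first path in
  which they appear; cumulative precision/recall over that ordering (edges
  that are neither positive nor sampled negative are skipped), summarized
  by the F1 series and compared between methods with a one-sided
  Mann-Whitney U test;
* **path-local** — *PosFrac*, the within-path fraction of positive edges
  (every non-positive edge counts against the path), averaged over
  non-overlapping windows of paths.  Unlike precision/recall this credits a
  positive every time it appears, so it characterizes individual paths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .interactome import Edge, Interactome
from .ksp import RankedReconstruction

__all__ = [
    "PathwayGroundTruth",
    "EvaluationResult",
    "RankedEdge",
    "rank_edges_by_first_path",
    "sample_pathway_negatives",
    "precision_recall",
    "f1_series",
    "posfrac",
    "mwu_test",
    "aggregate",
    "evaluate",
]


@dataclass(frozen=True)
class PathwayGroundTruth:
    """Positive (pathway) edges, sampled negatives, and pathway endpoints."""

    positives: frozenset[Edge]
    negatives: frozenset[Edge] = frozenset()
    receptors: frozenset[str] = frozenset()
    trs: frozenset[str] = frozenset()
    undirected: bool = False

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positive and negative edge sets overlap")

    def is_positive(self, edge: Edge) -> bool:
        if edge in self.positives:
            return True
        return self.undirected and (edge[1], edge[0]) in self.positives

    def is_negative(self, edge: Edge) -> bool:
        if edge in self.negatives:
            return True
        return self.undirected and (edge[1], edge[0]) in self.negatives


@dataclass(frozen=True)
class RankedEdge:
    """An interaction keyed by the first path it appears in."""

    edge: Edge
    path_index: int
    position: int


def rank_edges_by_first_path(rec: RankedReconstruction) -> list[RankedEdge]:
    """Order each distinct interaction by the index of the path in which it
    first appears (and its position within that path)."""
    if not rec.paths:
        raise ValueError("empty reconstruction")
    seen: set[Edge] = set()
    out: list[RankedEdge] = []
    for i, p in enumerate(rec.paths):
        for j, e in enumerate(p.edges):
            if e not in seen:
                seen.add(e)
                out.append(RankedEdge(e, i, j))
    return out


def sample_pathway_negatives(
    g: Interactome,
    positives: Iterable[Edge],
    ratio: int = 50,
    seed: int | None = None,
) -> frozenset[Edge]:
    """Seeded uniform sample of interactome edges outside the positives, at
    ``ratio`` negatives per positive (all candidates if the pool is short)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    positives = frozenset(tuple(e) for e in positives)
    pool = sorted(e for e in g.graph.edges if e not in positives)
    want = ratio * len(positives)
    if len(pool) <= want:
        if len(pool) < want:
            warnings.warn(f"negative pool ({len(pool)}) smaller than requested ({want})")
        return frozenset(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=want, replace=False)
    return frozenset(pool[i] for i in idx)


def precision_recall(
    edges: Sequence[RankedEdge] | Sequence[Edge],
    gt: PathwayGroundTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative precision/recall along a ranked edge list.

    Edges that are neither positive nor sampled negative are skipped
    entirely (they contribute to neither numerator nor denominator).
    Returns ``(precision, recall)`` arrays with one point per labelled edge.
    """
    if not gt.positives:
        raise ValueError("ground truth has no positive edges")
    tp = fp = 0
    pre, rec = [], []
    total_pos = len(gt.positives)
    for item in edges:
        e = item.edge if isinstance(item, RankedEdge) else tuple(item)
        if gt.is_positive(e):
            tp += 1
        elif gt.is_negative(e):
            fp += 1
        else:
            continue
        pre.append(tp / (tp + fp))
        rec.append(tp / total_pos)
    return np.asarray(pre), np.asarray(rec)


def f1_series(precision: np.ndarray, recall: np.ndarray) -> np.ndarray:
    """Pointwise harmonic mean ``2·pre·rec/(pre+rec)``; 0 where both are 0."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    denom = precision + recall
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = 2.0 * precision[nz] * recall[nz] / denom[nz]
    return out


def posfrac(
    rec: RankedReconstruction,
    gt: PathwayGroundTruth,
    window: int = 100,
) -> np.ndarray:
    """Window means of the within-path fraction of positive edges.

    Every non-positive edge of a path counts against it (no negative
    subsampling here).  The final partial window is averaged over its
    actual size.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    fracs = np.array(
        [
            sum(gt.is_positive(e) for e in p.edges) / len(p.edges)
            for p in rec.paths
        ]
    )
    return np.array(
        [fracs[i : i + window].mean() for i in range(0, len(fracs), window)]
    )


def mwu_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mann-Whitney U test for unpaired samples; returns ``(U, p)``.

    The p-value is exact (full rank-split enumeration) when both samples
    have at most 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"undefined alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def aggregate(
    rankings: Mapping[str, Sequence[RankedEdge]],
    gts: Mapping[str, PathwayGroundTruth],
) -> tuple[np.ndarray, np.ndarray]:
    """Micro-aggregated precision/recall across pathways.

    Pathway-tagged edges are pooled and ordered by first-appearance path
    index, ties across pathways broken by pathway name (then by position in
    the path); cumulative precision/recall uses each edge's own pathway's
    labels and the total positive count as recall denominator.
    """
    if not rankings:
        raise ValueError("need at least one pathway")
    if set(rankings) != set(gts):
        raise ValueError("rankings and ground truths must cover the same pathways")
    pooled: list[tuple[int, str, int, Edge]] = []
    for name, edges in rankings.items():
        for re_ in edges:
            pooled.append((re_.path_index, name, re_.position, re_.edge))
    pooled.sort(key=lambda t: (t[0], t[1], t[2]))
    total_pos = sum(len(gt.positives) for gt in gts.values())
    if total_pos == 0:
        raise ValueError("no positive edges in any pathway")
    tp = fp = 0
    pre, rec = [], []
    for _, name, _, e in pooled:
        gt = gts[name]
        if gt.is_positive(e):
            tp += 1
        elif gt.is_negative(e):
            fp += 1
        else:
            continue
        pre.append(tp / (tp + fp))
        rec.append(tp / total_pos)
    return np.asarray(pre), np.asarray(rec)


@dataclass
class EvaluationResult:
    """Bundle of global and path-local assessment series for one method."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    posfrac: np.ndarray
    mwu: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "posfrac": self.posfrac.tolist(),
            "mwu": self.mwu,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(
    rec: RankedReconstruction,
    gt: PathwayGroundTruth,
    window: int = 100,
) -> EvaluationResult:
    """Full assessment of one reconstruction against one pathway."""
    ranked = rank_edges_by_first_path(rec)
    pre, rc = precision_recall(ranked, gt)
    return EvaluationResult(
        precision=pre,
        recall=rc,
        f1=f1_series(pre, rc),
        posfrac=posfrac(rec, gt, window=window),
        provenance={
            "method": rec.provenance.get("method"),
            "window": window,
            "n_paths": len(rec),
            "n_positives": len(gt.positives),
            "n_negatives": len(gt.negatives),
            "aggregation": "micro",
        },
    )
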