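"""Weighted, directed protein-protein interactomes.

An interactome is a directed graph whose nodes are protein identifiers and
whose edges are interactions weighted by confidence ``w in (0, 1]``.  Each
edge may additionally carry a set of evidence-type labels (the experimental
or database provenance of the interaction) and a ComPPI-style interaction
score in ``[0, 1]`` giving the probability that the interaction occurs
inside the cell.

The module provides:

* TSV reading/writing of interactomes (columns ``tail  head  weight
  [evidence]  [interaction_score]``, ``#`` comments);
* evidence-based Bayesian edge weighting: per-evidence-type positive
  probabilities estimated against positive/negative edge sets, combined by
  noisy-OR and capped at a weight ceiling;
* seeded negative-edge sampling at a fixed ratio to the positives;
* the weight-coarseness statistic (the fraction of edges covered by the
  most frequent distinct weight values) that quantifies how heavily a
  network's confidence scores are tied.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Interactome",
    "EvidenceModel",
    "read_interactome",
    "write_interactome",
    "estimate_evidence_probabilities",
    "weight_edges",
    "sample_negative_edges",
    "weight_distribution",
]

Edge = tuple[str, str]

#: GO term "regulation of signal transduction", the default positive annotation.
DEFAULT_POSITIVE_ANNOTATION = "GO:0009966"


class Interactome:
    """Directed weighted interaction network.

    Thin wrapper around a :class:`networkx.DiGraph` that enforces the
    interactome invariants: weights strictly in ``(0, 1]``, no self loops,
    at most one directed edge per ordered pair.  Edge attributes are
    ``weight`` (float), ``evidence`` (frozenset of labels, possibly empty)
    and ``interaction_score`` (float in ``[0, 1]`` or ``None``).
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        isolated_nodes: Iterable[str] = (),
    ) -> "Interactome":
        """Build an interactome from ``(tail, head, weight[, evidence[, score]])`` tuples.

        Duplicate ordered pairs are collapsed keeping the maximum weight and
        the union of evidence labels; self loops and zero-weight edges are
        dropped with a warning; weights outside ``[0, 1]`` raise.
        """
        g = nx.DiGraph()
        for row in edges:
            u, v, w = row[0], row[1], float(row[2])
            ev = frozenset(row[3]) if len(row) > 3 and row[3] is not None else frozenset()
            score = float(row[4]) if len(row) > 4 and row[4] is not None else None
            if u == v:
                warnings.warn(f"dropping self-loop {u}->{v}")
                continue
            if w < 0.0 or w > 1.0:
                raise ValueError(f"edge {u}->{v}: weight {w} outside (0, 1]")
            if w == 0.0:
                warnings.warn(f"dropping zero-weight edge {u}->{v}")
                continue
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"edge {u}->{v}: interaction score {score} outside [0, 1]")
            if g.has_edge(u, v):
                d = g[u][v]
                d["weight"] = max(d["weight"], w)
                d["evidence"] = d["evidence"] | ev
                if score is not None:
                    prev = d.get("interaction_score")
                    d["interaction_score"] = score if prev is None else max(prev, score)
            else:
                g.add_edge(u, v, weight=w, evidence=ev, interaction_score=score)
        for n in isolated_nodes:
            g.add_node(n)
        return cls(g)

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[Edge]:
        return list(self.graph.edges)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def evidence(self, u: str, v: str) -> frozenset:
        return self.graph[u][v]["evidence"]

    def interaction_score(self, u: str, v: str) -> float | None:
        return self.graph[u][v].get("interaction_score")

    def copy(self) -> "Interactome":
        return Interactome(self.graph.copy())

    def __contains__(self, edge: Edge) -> bool:
        return self.graph.has_edge(*edge)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return nx.utils.graphs_equal(self.graph, other.graph)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "tail": u,
                    "head": v,
                    "weight": d["weight"],
                    "evidence": "|".join(sorted(d["evidence"])),
                    "interaction_score": d.get("interaction_score"),
                }
            )
        return pd.DataFrame(rows, columns=["tail", "head", "weight", "evidence", "interaction_score"])


@dataclass
class EvidenceModel:
    """Per-evidence-type probabilities that an evidence label supports a
    true signaling interaction, estimated from positive/negative edge sets.

    ``probabilities[t]`` is the smoothed fraction of labelled training edges
    carrying ``t`` that are positive.  ``weight_ceiling`` caps combined edge
    weights to avoid single edges dominating shortest-path costs.
    """

    probabilities: dict[str, float]
    positives: frozenset[Edge]
    negatives: frozenset[Edge]
    pseudocount: float = 1.0
    negative_ratio: int = 10
    weight_ceiling: float = 0.75
    positive_annotation: str = DEFAULT_POSITIVE_ANNOTATION

    def probability(self, label: str) -> float:
        """Positive probability for ``label``; unseen labels fall back to the
        pseudocount-only estimate (0.5 for any positive pseudocount)."""
        if label in self.probabilities:
            return self.probabilities[label]
        if self.pseudocount > 0:
            return 0.5
        raise KeyError(f"evidence label {label!r} unknown and pseudocount is 0")


# ---------------------------------------------------------------------------
# I/O


def read_interactome(
    path,
    dialect: Mapping[str, int] | None = None,
) -> Interactome:
    """Read a TSV edge list into an :class:`Interactome`.

    Columns default to ``tail, head, weight[, evidence[, interaction_score]]``;
    ``dialect`` may remap column positions, e.g. ``{"tail": 1, "head": 0,
    "weight": 2}``.  Evidence labels are pipe-separated.  Lines starting with
    ``#`` are comments.  Malformed rows raise a :class:`ValueError` naming
    the line number.
    """
    dialect = dict(dialect) if dialect else {"tail": 0, "head": 1, "weight": 2, "evidence": 3, "interaction_score": 4}
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            try:
                u = parts[dialect["tail"]]
                v = parts[dialect["head"]]
                w = float(parts[dialect["weight"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
            ev: frozenset = frozenset()
            ecol = dialect.get("evidence")
            if ecol is not None and ecol < len(parts) and parts[ecol].strip():
                ev = frozenset(parts[ecol].split("|"))
            score = None
            scol = dialect.get("interaction_score")
            if scol is not None and scol < len(parts) and parts[scol].strip():
                score = float(parts[scol])
            if w < 0.0 or w > 1.0:
                raise ValueError(f"{path}: line {lineno}: weight {w} outside (0, 1]")
            rows.append((u, v, w, ev, score))
    return Interactome.from_edges(rows)


def write_interactome(g: Interactome, path) -> None:
    """Write ``g`` as a TSV edge list (tail, head, weight, evidence, score)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#tail\thead\tweight\tevidence\tinteraction_score\n")
        for u, v, d in sorted(g.graph.edges(data=True)):
            ev = "|".join(sorted(d["evidence"]))
            score = d.get("interaction_score")
            fh.write(f"{u}\t{v}\t{d['weight']:.17g}\t{ev}\t{'' if score is None else f'{score:.17g}'}\n")


# ---------------------------------------------------------------------------
# Evidence-based weighting


def estimate_evidence_probabilities(
    g: Interactome,
    positives: Iterable[Edge],
    negatives: Iterable[Edge],
    pseudocount: float = 1.0,
    negative_ratio: int = 10,
    weight_ceiling: float = 0.75,
) -> EvidenceModel:
    """Estimate, for each evidence type ``t``, the probability that ``t``
    supports positive (signaling-related) interactions.

    For each label the estimate is the additively smoothed count ratio
    ``p_t = (pos_t + a) / (pos_t + neg_t + 2a)`` with pseudocount ``a``,
    where ``pos_t``/``neg_t`` count positive/negative edges carrying ``t``.
    """
    positives = frozenset(tuple(e) for e in positives)
    negatives = frozenset(tuple(e) for e in negatives)
    if not positives:
        raise ValueError("empty positive edge set: evidence model undefined")
    if positives & negatives:
        raise ValueError("positive and negative edge sets overlap")
    pos_counts: Counter = Counter()
    neg_counts: Counter = Counter()
    for u, v, d in g.graph.edges(data=True):
        if (u, v) in positives:
            pos_counts.update(d["evidence"])
        elif (u, v) in negatives:
            neg_counts.update(d["evidence"])
    probs = {}
    for label in set(pos_counts) | set(neg_counts):
        pos_t, neg_t = pos_counts[label], neg_counts[label]
        denom = pos_t + neg_t + 2.0 * pseudocount
        if denom == 0:
            raise ValueError(f"label {label!r}: no counts and no pseudocount")
        probs[label] = (pos_t + pseudocount) / denom
    return EvidenceModel(
        probabilities=probs,
        positives=positives,
        negatives=negatives,
        pseudocount=pseudocount,
        negative_ratio=negative_ratio,
        weight_ceiling=weight_ceiling,
    )


def weight_edges(g: Interactome, model: EvidenceModel, default_label: str | None = None) -> Interactome:
    """Assign each edge the noisy-OR combination of its evidence
    probabilities, capped at the model's weight ceiling.

    ``w_uv = min(ceiling, 1 - prod_t (1 - p_t))`` over the edge's evidence
    labels.  Edges without labels use ``default_label`` if given, otherwise
    raise.  Resulting weights lie in ``(0, ceiling]``.
    """
    out = g.copy()
    for u, v, d in out.graph.edges(data=True):
        labels = d["evidence"]
        if not labels:
            if default_label is None:
                raise ValueError(f"edge {u}->{v} has no evidence labels and no default label was given")
            labels = frozenset({default_label})
        raw = 1.0 - math.prod(1.0 - model.probability(t) for t in labels)
        d["weight"] = min(model.weight_ceiling, raw)
    return out


def sample_negative_edges(
    g: Interactome,
    positives: Iterable[Edge],
    ratio: int = 10,
    seed: int | None = None,
    annotated_nodes: Iterable[str] = (),
) -> set[Edge]:
    """Uniformly sample negative edges at ``ratio`` times the positive count.

    Candidates are edges of ``g`` that are not positives and whose endpoints
    both lack the positive annotation (``annotated_nodes``).  If the pool is
    smaller than requested, all candidates are returned with a warning.
    Sampling is without replacement and reproducible under ``seed``.
    """
    if ratio <= 0:
        raise ValueError(f"negative sampling ratio must be positive, got {ratio}")
    positives = frozenset(tuple(e) for e in positives)
    annotated = set(annotated_nodes)
    pool = sorted(
        (u, v)
        for u, v in g.graph.edges
        if (u, v) not in positives and u not in annotated and v not in annotated
    )
    want = ratio * len(positives)
    if len(pool) <= want:
        if len(pool) < want:
            warnings.warn(
                f"negative candidate pool ({len(pool)}) smaller than requested ({want}); returning all"
            )
        return set(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=want, replace=False)
    return {pool[i] for i in idx}


def weight_distribution(g: Interactome, top_m: int) -> float:
    """Fraction of edges whose weight equals one of the ``top_m`` most
    frequent distinct weight values.

    This is the coarseness statistic behind tied path scores: when two or
    three weight values cover most of a network, products of edge weights
    collide and k-shortest-path rankings are dominated by ties.
    """
    if top_m < 1:
        raise ValueError(f"top_m must be >= 1, got {top_m}")
    n = g.n_edges()
    if n == 0:
        raise ValueError("empty interactome")
    counts = Counter(d["weight"] for _, _, d in g.graph.edges(data=True))
    # deterministic under frequency ties: prefer the larger weight value
    top = sorted(counts.items(), key=lambda kv: (-kv[1], -kv[0]))[:top_m]
    return sum(c for _, c in top) / n
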