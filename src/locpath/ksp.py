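"""PathLinker-style k-shortest-path pathway reconstruction.

Given a weighted directed interactome, a set of receptors ``R`` and a set of
transcriptional regulators ``T``, the reconstruction is the ranked list of
the k shortest loopless receptor-to-TR paths under the negative-log
transform of edge weights: a path's *reconstruction score* ``r`` is the
product of its edge weights, its cost is ``-ln r``, and the shortest path is
the one with the highest weight product.  The graph is augmented with a
super-source (unit-weight edges into every receptor) and a super-sink
(unit-weight edges out of every TR) so a single s-t search covers all
endpoint pairs; unit edges contribute zero cost and are stripped from the
returned paths.

Yen's algorithm is implemented with a fully deterministic tie order:
candidates are keyed by ``(cost, node sequence)``, and the Dijkstra
subroutine breaks cost ties lexicographically on the node sequence, so equal
cost paths always appear in lexicographic order regardless of platform.

Because many interactomes concentrate most edges on two or three distinct
weight values, reconstructions are dominated by runs of paths with exactly
equal scores; :func:`group_ties` partitions the ranked list into these tie
groups, the unit on which localization-based re-ranking operates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from heapq import heappush, heappop
from typing import Iterable, Sequence

import networkx as nx

from .interactome import Interactome

__all__ = [
    "Path",
    "RankedReconstruction",
    "augment",
    "yen_ksp",
    "group_ties",
    "reconstruct",
    "write_paths",
    "read_paths",
]

SUPER_SOURCE = "__source__"
SUPER_SINK = "__sink__"


@dataclass(frozen=True)
class Path:
    """A simple receptor-to-TR path.

    ``reconstruction_score`` is the product of edge weights and ``cost`` the
    sum of their negative natural logs; the two agree via exp/-ln up to
    floating-point roundoff.
    """

    nodes: tuple[str, ...]
    cost: float
    reconstruction_score: float

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path revisits a node: {self.nodes}")

    @classmethod
    def from_graph(cls, nodes: Sequence[str], g: nx.DiGraph) -> "Path":
        nodes = tuple(nodes)
        cost = 0.0
        score = 1.0
        for u, v in zip(nodes, nodes[1:]):
            w = g[u][v]["weight"]
            cost += -math.log(w)
            score *= w
        return cls(nodes, cost, score)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes, self.nodes[1:]))

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class RankedReconstruction:
    """Ordered list of k paths with non-increasing reconstruction scores,
    partitioned into contiguous tie groups, plus provenance."""

    paths: list[Path]
    tie_groups: list[tuple[int, int]] = field(default_factory=list)  # half-open [start, end)
    provenance: dict = field(default_factory=dict)
    signaling_costs: list[float] | None = None
    compartment_labels: list[tuple[str, ...] | None] | None = None

    def __post_init__(self):
        if not self.tie_groups and self.paths:
            self.tie_groups = group_ties(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    def scores(self) -> list[float]:
        return [p.reconstruction_score for p in self.paths]


# ---------------------------------------------------------------------------
# Graph augmentation


def augment(
    g: Interactome | nx.DiGraph,
    receptors: Iterable[str],
    trs: Iterable[str],
) -> nx.DiGraph:
    """Add a super-source feeding all receptors and a super-sink drained by
    all TRs, with weight-1 (zero-cost) edges.

    Receptors or TRs absent from the graph are skipped with a warning; if
    none of either set is present, raises.  Each edge of the returned graph
    carries a ``cost`` attribute ``-ln weight``.
    """
    graph = g.graph if isinstance(g, Interactome) else g
    aug = graph.copy()
    receptors, trs = set(receptors), set(trs)
    missing_r = receptors - set(graph.nodes)
    missing_t = trs - set(graph.nodes)
    if missing_r:
        warnings.warn(f"{len(missing_r)} receptor(s) not in interactome; ignored")
    if missing_t:
        warnings.warn(f"{len(missing_t)} TR(s) not in interactome; ignored")
    present_r = receptors - missing_r
    present_t = trs - missing_t
    if not present_r:
        raise ValueError("no receptor present in the interactome")
    if not present_t:
        raise ValueError("no transcriptional regulator present in the interactome")
    for r in present_r:
        aug.add_edge(SUPER_SOURCE, r, weight=1.0)
    for t in present_t:
        aug.add_edge(t, SUPER_SINK, weight=1.0)
    for u, v, d in aug.edges(data=True):
        d["cost"] = -math.log(d["weight"])
    return aug


# ---------------------------------------------------------------------------
# Yen's algorithm with deterministic tie order


def _dijkstra(
    g: nx.DiGraph,
    root: tuple[str, ...],
    root_cost: float,
    target: str,
    banned_nodes: frozenset[str],
    banned_edges: frozenset[tuple[str, str]],
) -> tuple[float, tuple[str, ...]] | None:
    """Cheapest extension of ``root`` to ``target``; cost ties broken by
    lexicographically smallest full node sequence.

    Costs accumulate left-to-right along the whole path so equal node
    sequences always produce bit-identical costs.
    """
    heap: list[tuple[float, tuple[str, ...]]] = [(root_cost, root)]
    done: set[str] = set()
    while heap:
        cost, path = heappop(heap)
        v = path[-1]
        if v in done:
            continue
        done.add(v)
        if v == target:
            return cost, path
        for u in g.successors(v):
            if u in done or u in banned_nodes or (v, u) in banned_edges or u in path:
                continue
            heappush(heap, (cost + g[v][u]["cost"], path + (u,)))
    return None


def yen_ksp(
    g: nx.DiGraph, source: str, target: str, k: int, tie_tol: float = 1e-9
) -> list[tuple[float, tuple[str, ...]]]:
    """Yen's k shortest loopless paths on a graph with ``cost`` edge attrs.

    Returns up to ``k`` ``(cost, nodes)`` pairs sorted by cost with
    equal-cost paths in lexicographic node order.  To make truncation at a
    tie boundary deterministic, enumeration continues past k until the
    candidate cost exceeds the k-th cost by more than ``tie_tol``; the
    collected paths are then sorted and cut at k, so the retained members
    of a boundary tie group are always the lexicographically smallest.
    Returns fewer than ``k`` pairs when the graph holds fewer simple
    source-target paths, and an empty list if the target is unreachable.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    first = _dijkstra(g, (source,), 0.0, target, frozenset(), frozenset())
    if first is None:
        return []
    accepted: list[tuple[float, tuple[str, ...]]] = []
    candidates: list[tuple[float, tuple[str, ...]]] = [first]
    seen: set[tuple[str, ...]] = {first[1]}
    while candidates:
        if len(accepted) >= k and candidates[0][0] > accepted[k - 1][0] + tie_tol:
            break
        accepted.append(heappop(candidates))
        _, prev = accepted[-1]
        root_cost = 0.0
        for i in range(len(prev) - 1):
            root = prev[: i + 1]
            banned_edges = {
                (p[i], p[i + 1])
                for _, p in accepted
                if len(p) > i + 1 and p[: i + 1] == root
            }
            banned_nodes = frozenset(root[:-1])
            cand = _dijkstra(g, root, root_cost, target, banned_nodes, frozenset(banned_edges))
            if cand is not None and cand[1] not in seen:
                seen.add(cand[1])
                heappush(candidates, cand)
            root_cost += g[prev[i]][prev[i + 1]]["cost"]
    accepted.sort()
    return accepted[:k]


def group_ties(paths: Sequence[Path], tol: float = 1e-9) -> list[tuple[int, int]]:
    """Partition a score-sorted path list into maximal runs of equal
    reconstruction score.

    Equality is judged on the cost scale within absolute tolerance ``tol``
    (products of identical coarse weights must collapse into one group
    despite floating-point reassociation).  Raises if the input is not
    sorted by non-decreasing cost.
    """
    groups: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(paths) + 1):
        if i == len(paths):
            groups.append((start, i))
            break
        if paths[i].cost < paths[i - 1].cost - tol:
            raise ValueError("paths are not sorted by non-increasing reconstruction score")
        if abs(paths[i].cost - paths[start].cost) > tol:
            groups.append((start, i))
            start = i
    return groups


# ---------------------------------------------------------------------------
# End-to-end reconstruction


def reconstruct(
    g: Interactome,
    receptors: Iterable[str],
    trs: Iterable[str],
    k: int = 20000,
    tie_tol: float = 1e-9,
) -> RankedReconstruction:
    """Full PathLinker-style reconstruction: augment, run Yen's algorithm,
    strip the super nodes, and partition into tie groups."""
    receptors, trs = set(receptors), set(trs)
    aug = augment(g, receptors, trs)
    raw = yen_ksp(aug, SUPER_SOURCE, SUPER_SINK, k)
    paths = []
    for _, nodes in raw:
        inner = nodes[1:-1]
        paths.append(Path.from_graph(inner, g.graph))
    return RankedReconstruction(
        paths=paths,
        tie_groups=group_ties(paths, tol=tie_tol),
        provenance={
            "method": "PathLinker",
            "k": k,
            "tie_tolerance": tie_tol,
            "n_receptors": len(receptors),
            "n_trs": len(trs),
        },
    )


# ---------------------------------------------------------------------------
# Paths TSV I/O


def write_paths(rec: RankedReconstruction, path) -> None:
    """Write a reconstruction as TSV: rank, cost, reconstruction_score,
    pipe-separated nodes, and (when present) signaling_cost + compartments."""
    with_sig = rec.signaling_costs is not None
    with open(path, "wt", encoding="utf-8") as fh:
        cols = "#rank\tcost\treconstruction_score\tnodes"
        if with_sig:
            cols += "\tsignaling_cost\tcompartments"
        fh.write(cols + "\n")
        for i, p in enumerate(rec.paths):
            row = f"{i + 1}\t{p.cost:.17g}\t{p.reconstruction_score:.17g}\t{'|'.join(p.nodes)}"
            if with_sig:
                s = rec.signaling_costs[i]
                labels = rec.compartment_labels[i] if rec.compartment_labels else None
                row += f"\t{'inf' if math.isinf(s) else f'{s:.17g}'}"
                row += f"\t{'|'.join(labels) if labels else ''}"
            fh.write(row + "\n")


def read_paths(path) -> RankedReconstruction:
    """Read a reconstruction written by :func:`write_paths`."""
    paths: list[Path] = []
    sig: list[float] = []
    labels: list[tuple[str, ...] | None] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            cost, score = float(parts[1]), float(parts[2])
            nodes = tuple(parts[3].split("|"))
            paths.append(Path(nodes, cost, score))
            if len(parts) > 4:
                sig.append(float(parts[4]))
                labels.append(tuple(parts[5].split("|")) if len(parts) > 5 and parts[5] else None)
    rec = RankedReconstruction(paths=paths, tie_groups=group_ties(paths))
    if sig:
        rec.signaling_costs = sig
        rec.compartment_labels = labels
    return rec
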