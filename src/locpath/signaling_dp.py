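"""Compartment dynamic program: path signaling scores and tie re-ranking.

For a path ``P = (v_1, ..., v_m)`` the *signaling score* is the minimum
total localization cost of assigning each node a cellular compartment such
that the assignment starts ExtMem-feasible, ends in the Nucleus, and
advances only along the allowed compartment transitions.  Signaling may
advance between consecutive proteins in two ways: the pair interacts in a
shared compartment, or one protein traverses between compartments — in
which case that protein pays the localization cost of *both* compartments.

With costs ``l(v, c) = -log score(v, c)``, the default three-compartment
recurrence for interior nodes j = 2..m is::

    s(v_j, ext) = s(v_{j-1}, ext) + l(v_j, ext)
    s(v_j, cyt) = min[ s(v_{j-1}, ext) + l(v_j, ext),
                       s(v_{j-1}, ext) + l(v_{j-1}, cyt),
                       s(v_{j-1}, cyt) ] + l(v_j, cyt)
    s(v_j, nuc) = min[ s(v_{j-1}, cyt) + l(v_j, cyt),
                       s(v_{j-1}, cyt) + l(v_{j-1}, nuc),
                       s(v_{j-1}, nuc) ] + l(v_j, nuc)

with base cases ``s(v_1, ext) = l(v_1, ext)`` and
``s(v_1, cyt) = s(v_1, nuc) = inf``; the path score is ``s(v_m, nuc)``.
The recurrences here are generated from the
:class:`~locpath.localization.CompartmentModel` transition relation rather
than hard-coded, so longer or different compartment chains (mitochondria,
secretory vesicles) work unchanged as long as transitions are memoryless.

A direct consequence of the base cases is that two-node paths (single
interactions) always score ``+inf``: the first node must start at the
membrane and the last must reach the nucleus, but no single transition
spans the chain.

Re-ranking: within each tie group of a reconstruction (paths with equal
reconstruction score), paths are reordered by ascending signaling cost
(stable on the original rank); group boundaries and between-group order
never change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .ksp import Path, RankedReconstruction
from .localization import CompartmentModel, LocalizationTable

__all__ = [
    "SignalingAssignment",
    "signaling_score",
    "brute_force_signaling_score",
    "rerank",
]


@dataclass(frozen=True)
class SignalingAssignment:
    """Optimal compartment labeling of one path.

    ``cost`` is the signaling score (total localization cost, ``+inf`` when
    no feasible assignment exists); ``labels`` gives one optimal compartment
    per node, or ``None`` when the cost is infinite.
    """

    nodes: tuple[str, ...]
    cost: float
    labels: tuple[str, ...] | None

    @property
    def finite(self) -> bool:
        return math.isfinite(self.cost)


def signaling_score(
    path: Path | Sequence[str],
    table: LocalizationTable,
    model: CompartmentModel | None = None,
    base: float = math.e,
) -> SignalingAssignment:
    """Dynamic program for the optimal compartment assignment of a path.

    Runs in time linear in the path length (times the squared number of
    compartments).  ``base`` sets the log base of the localization costs;
    it rescales the score but never changes the optimal assignment.
    """
    model = model or CompartmentModel.default()
    nodes = tuple(path.nodes) if isinstance(path, Path) else tuple(path)
    if len(nodes) < 2:
        raise ValueError("signaling score requires a path of at least two nodes")

    def cost(v: str, c: str) -> float:
        return table.cost(v, c, base=base)

    comps = model.compartments
    # s[c]: best cost of the path so far ending with the current node in c
    s = {c: (cost(nodes[0], model.start) if c == model.start else math.inf) for c in comps}
    # back[j][c] = compartment of node j-1 in the optimal route to (j, c)
    back: list[dict[str, str | None]] = [{c: None for c in comps}]

    for j in range(1, len(nodes)):
        prev_v, v = nodes[j - 1], nodes[j]
        new_s: dict[str, float] = {}
        back_j: dict[str, str | None] = {}
        for c in comps:
            best = math.inf
            best_prev: str | None = None
            # predecessors in chain order: ties prefer the earliest
            # compartment, which keeps transitions as late as possible
            for a in model.predecessors(c):
                if a == c:
                    route = s[a]
                else:
                    # pair interacts in a (v traverses) or in c (prev_v traverses)
                    route = s[a] + min(cost(v, a), cost(prev_v, c))
                if route < best:
                    best, best_prev = route, a
            new_s[c] = best + cost(v, c)
            back_j[c] = best_prev
        s = new_s
        back.append(back_j)

    total = s[model.end]
    if not math.isfinite(total):
        return SignalingAssignment(nodes, math.inf, None)
    labels = [model.end]
    for j in range(len(nodes) - 1, 0, -1):
        labels.append(back[j][labels[-1]])  # type: ignore[arg-type]
    labels.reverse()
    return SignalingAssignment(nodes, total, tuple(labels))


def brute_force_signaling_score(
    path: Path | Sequence[str],
    table: LocalizationTable,
    model: CompartmentModel | None = None,
    base: float = math.e,
) -> float:
    """Exhaustive-enumeration oracle for :func:`signaling_score`.

    Enumerates every compartment labeling consistent with the transition
    relation (start at the model start, end at the model end) and, for each
    compartment change, both ways the pair can bridge it (either protein
    traverses and pays both compartments); returns the minimum total cost.
    Intended for short paths only.
    """
    model = model or CompartmentModel.default()
    nodes = tuple(path.nodes) if isinstance(path, Path) else tuple(path)
    if len(nodes) < 2:
        raise ValueError("signaling score requires a path of at least two nodes")
    if len(nodes) > 10:
        raise ValueError("brute force oracle limited to paths of <= 10 nodes")

    def cost(v: str, c: str) -> float:
        return table.cost(v, c, base=base)

    def labelings(prefix: tuple[str, ...]):
        j = len(prefix)
        if j == len(nodes):
            if prefix[-1] == model.end:
                yield prefix
            return
        options = model.compartments if j > 0 else (model.start,)
        for c in options:
            if j > 0 and not model.allows(prefix[-1], c):
                continue
            yield from labelings(prefix + (c,))

    best = math.inf
    for labeling in labelings(()):
        node_cost = sum(cost(v, c) for v, c in zip(nodes, labeling))
        changes = [
            j for j in range(1, len(nodes)) if labeling[j] != labeling[j - 1]
        ]
        # each change: either v_j visits the old compartment or v_{j-1} the new
        for routes in product((0, 1), repeat=len(changes)):
            extra = 0.0
            for j, r in zip(changes, routes):
                if r == 0:
                    extra += cost(nodes[j], labeling[j - 1])
                else:
                    extra += cost(nodes[j - 1], labeling[j])
            best = min(best, node_cost + extra)
    return best


def rerank(
    rec: RankedReconstruction,
    table: LocalizationTable,
    model: CompartmentModel | None = None,
) -> RankedReconstruction:
    """Re-order each tie group by ascending signaling cost (stable).

    Between-group order and group boundaries are untouched; paths with
    infinite signaling cost sink to the bottom of their group.  The result
    carries per-path signaling costs and optimal compartment labels.
    """
    model = model or CompartmentModel.default()
    assignments = [signaling_score(p, table, model) for p in rec.paths]
    order = list(range(len(rec.paths)))
    for start, end in rec.tie_groups:
        block = sorted(order[start:end], key=lambda i: (assignments[i].cost, i))
        order[start:end] = block
    return RankedReconstruction(
        paths=[rec.paths[i] for i in order],
        tie_groups=list(rec.tie_groups),
        provenance={**rec.provenance, "method": "locpath", "compartments": model.compartments},
        signaling_costs=[assignments[i].cost for i in order],
        compartment_labels=[assignments[i].labels for i in order],
    )
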