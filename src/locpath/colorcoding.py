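"""Color-coding search for compartment-ordered receptor-to-TR paths.

Color-coding is a randomized technique for finding simple paths: every node
is assigned a uniform random color from ``{1..l}`` and only *colorful* paths
(all l vertices with pairwise distinct colors) are accepted, which
guarantees simplicity.  A single random coloring colors a fixed l-vertex
path colorfully with probability ``l!/l^l``, so many independent colorings
are needed to find an optimum with high probability.

The variant implemented here additionally constrains paths by a binarized
compartment model: a path is accepted only if its vertices admit a
compartment labeling that starts at the model's start compartment, ends at
its end compartment, and moves only along allowed transitions, where a node
may occupy a compartment exactly when its localization score there is
positive.

Two search modes are provided:

* :func:`cc_iterate` — classic color coding: repeat random colorings and
  keep the best (lowest-cost) colorful, compartment-valid path found;
* :func:`yen_cc` — a k-shortest-paths hybrid: Yen's spur/root scheme where
  every spur completion must itself be colorful and compartment-ordered,
  with a fresh random coloring per trial and a capped trial budget per spur.
  Unlike the localization-aware re-ranking pipeline, Yen_CC has no second
  score to break ties with, so equal-cost paths are reported in the order
  the search produced them.

The colorful search itself is exact for a given coloring: a dynamic program
over ``(node, used-color subset, compartment)`` states finds the cheapest
colorful compartment-valid path of exactly l vertices, so randomness enters
only through the colorings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from heapq import heappush, heappop
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .interactome import Interactome
from .ksp import Path, RankedReconstruction, group_ties
from .localization import CompartmentModel, LocalizationTable

__all__ = [
    "Coloring",
    "binarize_localization",
    "find_colorful_path",
    "cc_iterate",
    "yen_cc",
    "required_trials",
]

MAX_PATH_LENGTH = 12  # 2^l color-subset table


@dataclass(frozen=True)
class Coloring:
    """A random assignment of colors ``0..l-1`` to nodes."""

    colors: Mapping[str, int]
    l: int
    seed: int | None = None

    @classmethod
    def random(cls, nodes: Iterable[str], l: int, rng: np.random.Generator) -> "Coloring":
        nodes = sorted(nodes)
        draw = rng.integers(0, l, size=len(nodes))
        return cls(colors=dict(zip(nodes, (int(c) for c in draw))), l=l)

    def __getitem__(self, node: str) -> int:
        return self.colors[node]


def binarize_localization(
    table: LocalizationTable, model: CompartmentModel
) -> dict[str, frozenset[str]]:
    """Per-protein compartment membership: compartments with score > 0."""
    return {
        p: frozenset(c for c in model.compartments if table.score(p, c) > 0.0)
        for p in table.proteins()
    }


def _graph_of(g: Interactome | nx.DiGraph) -> nx.DiGraph:
    graph = g.graph if isinstance(g, Interactome) else g
    for _, _, d in graph.edges(data=True):
        if "cost" not in d:
            d["cost"] = -math.log(d["weight"])
    return graph


def _best_colorful_completion(
    graph: nx.DiGraph,
    root: tuple[str, ...],
    root_cost: float,
    targets: frozenset[str],
    l_total: int,
    coloring: Coloring,
    model: CompartmentModel,
    membership: Mapping[str, frozenset[str]],
    banned_edges: frozenset[tuple[str, str]] = frozenset(),
) -> tuple[float, tuple[str, ...]] | None:
    """Cheapest colorful, compartment-valid path of exactly ``l_total``
    vertices extending ``root`` to any target, under one coloring.

    ``root`` must itself be colorful; its compartment labelings determine
    the feasible start states of the extension.  Cost ties break
    lexicographically on the node sequence.
    """
    # colors of the root must be pairwise distinct
    root_colors = [coloring[v] for v in root]
    if len(set(root_colors)) != len(root_colors):
        return None
    mask0 = 0
    for c in root_colors:
        mask0 |= 1 << c

    # feasible compartments at each root node under the binarized model
    comps = {model.start} & set(membership.get(root[0], frozenset()))
    for v in root[1:]:
        comps = {
            b
            for b in membership.get(v, frozenset())
            if any(model.allows(a, b) for a in comps)
        }
    if not comps:
        return None

    # DP over (node, color mask, compartment) -> best (cost, path); layered
    # by path length so each state is extended exactly once
    layer: dict[tuple[str, int, str], tuple[float, tuple[str, ...]]] = {
        (root[-1], mask0, c): (root_cost, root) for c in comps
    }
    for _ in range(l_total - len(root)):
        nxt: dict[tuple[str, int, str], tuple[float, tuple[str, ...]]] = {}
        for (v, mask, a), (cost, path) in layer.items():
            for u in graph.successors(v):
                if (v, u) in banned_edges:
                    continue
                cu = coloring.colors.get(u)
                if cu is None or mask & (1 << cu):
                    continue
                for b in membership.get(u, frozenset()):
                    if not model.allows(a, b):
                        continue
                    key = (u, mask | (1 << cu), b)
                    cand = (cost + graph[v][u]["cost"], path + (u,))
                    if key not in nxt or cand < nxt[key]:
                        nxt[key] = cand
        layer = nxt
        if not layer:
            return None
    best: tuple[float, tuple[str, ...]] | None = None
    for (v, _, c), cand in layer.items():
        if v in targets and c == model.end and (best is None or cand < best):
            best = cand
    return best


def find_colorful_path(
    g: Interactome | nx.DiGraph,
    receptors: Iterable[str],
    trs: Iterable[str],
    l: int,
    coloring: Coloring,
    model: CompartmentModel | None = None,
    membership: Mapping[str, frozenset[str]] | None = None,
    table: LocalizationTable | None = None,
) -> Path | None:
    """Minimum-cost colorful, compartment-ordered path of exactly ``l``
    vertices from a receptor to a TR under one coloring, or ``None``."""
    if not 2 <= l <= MAX_PATH_LENGTH:
        raise ValueError(f"path length l must be in [2, {MAX_PATH_LENGTH}], got {l}")
    model = model or CompartmentModel.default()
    if membership is None:
        if table is None:
            raise ValueError("provide either membership or a localization table")
        membership = binarize_localization(table, model)
    graph = _graph_of(g)
    targets = frozenset(t for t in trs if t in graph)
    best: tuple[float, tuple[str, ...]] | None = None
    for r in sorted(set(receptors) & set(graph.nodes)):
        cand = _best_colorful_completion(
            graph, (r,), 0.0, targets, l, coloring, model, membership
        )
        if cand is not None and (best is None or cand < best):
            best = cand
    if best is None:
        return None
    return Path.from_graph(best[1], graph)


def required_trials(l: int, success_prob: float) -> int:
    """Colorings needed so an l-vertex path is colorful at least once with
    probability ``success_prob`` (single-trial success rate ``l!/l^l``)."""
    if not 0.0 < success_prob < 1.0:
        raise ValueError("success_prob must be in (0, 1)")
    single = math.factorial(l) / l**l
    return math.ceil(math.log(1.0 - success_prob) / math.log(1.0 - single))


def cc_iterate(
    g: Interactome | nx.DiGraph,
    receptors: Iterable[str],
    trs: Iterable[str],
    l: int,
    trials: int | None = None,
    success_prob: float | None = None,
    seed: int | None = None,
    model: CompartmentModel | None = None,
    table: LocalizationTable | None = None,
    membership: Mapping[str, frozenset[str]] | None = None,
) -> Path | None:
    """Best compartment-valid colorful path over repeated random colorings.

    Either ``trials`` or ``success_prob`` must be given; with
    ``success_prob`` the trial count is ``ceil(ln(1/(1-p)) / -ln(1 - l!/l^l))``.
    Deterministic under a fixed seed.
    """
    if trials is None:
        if success_prob is None:
            raise ValueError("provide trials or success_prob")
        trials = required_trials(l, success_prob)
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    model = model or CompartmentModel.default()
    if membership is None:
        if table is None:
            raise ValueError("provide either membership or a localization table")
        membership = binarize_localization(table, model)
    graph = _graph_of(g)
    rng = np.random.default_rng(seed)
    best: Path | None = None
    for _ in range(trials):
        coloring = Coloring.random(graph.nodes, l, rng)
        cand = find_colorful_path(
            graph, receptors, trs, l, coloring, model, membership=membership
        )
        if cand is not None and (
            best is None or (cand.cost, cand.nodes) < (best.cost, best.nodes)
        ):
            best = cand
    return best


def yen_cc(
    g: Interactome | nx.DiGraph,
    receptors: Iterable[str],
    trs: Iterable[str],
    k: int,
    l_range: tuple[int, int] = (2, 8),
    model: CompartmentModel | None = None,
    table: LocalizationTable | None = None,
    membership: Mapping[str, frozenset[str]] | None = None,
    trials_per_spur: int = 100,
    seed: int | None = None,
) -> RankedReconstruction:
    """k best compartment-ordered colorful paths via Yen's spur search.

    Each spur completion is sought with ``trials_per_spur`` fresh random
    colorings for every candidate total length in ``l_range``; a completion
    is accepted only if the whole path (root + completion) is colorful and
    compartment-valid.  Paths are returned in non-decreasing cost order;
    equal-cost paths keep the order the search produced.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lmin, lmax = l_range
    if not 2 <= lmin <= lmax <= MAX_PATH_LENGTH:
        raise ValueError(f"l_range must satisfy 2 <= lmin <= lmax <= {MAX_PATH_LENGTH}")
    model = model or CompartmentModel.default()
    if membership is None:
        if table is None:
            raise ValueError("provide either membership or a localization table")
        membership = binarize_localization(table, model)
    graph = _graph_of(g)
    receptors = sorted(set(receptors) & set(graph.nodes))
    targets = frozenset(t for t in trs if t in graph)
    rng = np.random.default_rng(seed)

    def search(
        root: tuple[str, ...], root_cost: float, banned_edges: frozenset
    ) -> tuple[float, tuple[str, ...]] | None:
        best: tuple[float, tuple[str, ...]] | None = None
        for l_total in range(max(lmin, len(root)), lmax + 1):
            if l_total < len(root) + (0 if root[-1] in targets else 1):
                continue
            for _ in range(trials_per_spur):
                coloring = Coloring.random(graph.nodes, l_total, rng)
                cand = _best_colorful_completion(
                    graph, root, root_cost, targets, l_total, coloring,
                    model, membership, banned_edges,
                )
                if cand is not None and (best is None or cand < best):
                    best = cand
        return best

    # initial paths: best completion from each receptor
    accepted: list[tuple[float, tuple[str, ...]]] = []
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = set()
    for r in receptors:
        cand = search((r,), 0.0, frozenset())
        if cand is not None and cand[1] not in seen:
            seen.add(cand[1])
            heappush(candidates, cand)
    while candidates and len(accepted) < k:
        accepted.append(heappop(candidates))
        _, prev = accepted[-1]
        root_cost = 0.0
        for i in range(len(prev) - 1):
            root = prev[: i + 1]
            banned = {
                (p[i], p[i + 1])
                for _, p in accepted
                if len(p) > i + 1 and p[: i + 1] == root
            }
            # root nodes cannot be revisited: their colors are already used
            cand = search(root, root_cost, frozenset(banned))
            if cand is not None and cand[1] not in seen:
                seen.add(cand[1])
                heappush(candidates, cand)
            root_cost += graph[prev[i]][prev[i + 1]]["cost"]
        # new receptors may yield alternatives equal to removed firsts; the
        # per-receptor initial candidates above already cover them
    paths = [Path.from_graph(nodes, graph) for _, nodes in accepted]
    return RankedReconstruction(
        paths=paths,
        tie_groups=group_ties(paths),
        provenance={
            "method": "Yen_CC",
            "k": k,
            "l_range": list(l_range),
            "trials_per_spur": trials_per_spur,
            "seed": seed,
        },
    )
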