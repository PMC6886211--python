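"""Protein subcellular localization scores and the compartment flow model.

ComPPI-style localization tables assign each protein a score in ``[0, 1]``
per cellular compartment — the likelihood the protein resides there.  The
default signaling model uses three compartments: *ExtMem* (extracellular
fluid and cell membrane, aggregated), *Cytosol*, and *Nucleus*, with
signaling flowing unidirectionally ExtMem -> Cytosol -> Nucleus.  Scores are
converted to additive costs by a negative log transform, so compartment
assignments can be optimized by summation; a zero score costs infinity.

The interaction-score filter removes interactome edges whose ComPPI
interaction score is zero — interactions that are biophysically possible
but unlikely to occur anywhere inside the cell given where the two proteins
localize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .interactome import Edge, Interactome

__all__ = [
    "EXTMEM",
    "CYTOSOL",
    "NUCLEUS",
    "MITOCHONDRIA",
    "SECRETORY",
    "CompartmentModel",
    "LocalizationTable",
    "read_localization",
    "filter_interactome",
    "localization_cost",
]

EXTMEM = "ExtMem"
CYTOSOL = "Cytosol"
NUCLEUS = "Nucleus"
MITOCHONDRIA = "Mitochondria"
SECRETORY = "Secretory"


@dataclass(frozen=True)
class CompartmentModel:
    """Ordered compartments plus the memoryless transition relation between
    consecutive nodes of a path.

    The default is the chain ExtMem -> Cytosol -> Nucleus with
    self-transitions and single forward steps only: signaling may stay in a
    compartment or advance to the next one, never skip or go back.  Custom
    chains (e.g. including mitochondria or secretory vesicles) can be built
    with :meth:`chain` or by passing an explicit transition relation.
    """

    compartments: tuple[str, ...]
    transitions: frozenset[tuple[str, str]]
    start: str
    end: str

    def __post_init__(self):
        comps = set(self.compartments)
        if self.start not in comps or self.end not in comps:
            raise ValueError("start/end compartment not in compartment list")
        for a, b in self.transitions:
            if a not in comps or b not in comps:
                raise ValueError(f"transition ({a}, {b}) uses unknown compartment")

    @classmethod
    def chain(cls, compartments: Iterable[str]) -> "CompartmentModel":
        """Unidirectional chain: self-transitions plus one forward step."""
        comps = tuple(compartments)
        if len(comps) < 2:
            raise ValueError("need at least two compartments")
        trans = {(c, c) for c in comps}
        trans |= {(comps[i], comps[i + 1]) for i in range(len(comps) - 1)}
        return cls(comps, frozenset(trans), start=comps[0], end=comps[-1])

    @classmethod
    def default(cls) -> "CompartmentModel":
        return cls.chain((EXTMEM, CYTOSOL, NUCLEUS))

    def allows(self, a: str, b: str) -> bool:
        """Whether signaling may advance from a node in ``a`` to one in ``b``."""
        return (a, b) in self.transitions

    def predecessors(self, c: str) -> tuple[str, ...]:
        """Compartments from which ``c`` can be reached, in chain order."""
        return tuple(a for a in self.compartments if self.allows(a, c))

    def index(self, c: str) -> int:
        return self.compartments.index(c)


class LocalizationTable:
    """Per-protein, per-compartment localization scores.

    Missing proteins score 0 everywhere.  May optionally carry per-edge
    interaction scores (used by :func:`filter_interactome` when the
    interactome itself has none).
    """

    def __init__(
        self,
        scores: Mapping[str, Mapping[str, float]],
        compartments: tuple[str, ...] = (EXTMEM, CYTOSOL, NUCLEUS),
        edge_scores: Mapping[Edge, float] | None = None,
    ):
        self.compartments = tuple(compartments)
        self._scores: dict[str, dict[str, float]] = {}
        for protein, by_comp in scores.items():
            row = {}
            for c, s in by_comp.items():
                s = float(s)
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"{protein}: localization score {s} for {c} outside [0, 1]")
                row[c] = s
            self._scores[protein] = row
        self.edge_scores = dict(edge_scores) if edge_scores else {}

    def proteins(self) -> set[str]:
        return set(self._scores)

    def score(self, protein: str, compartment: str) -> float:
        if compartment not in self.compartments:
            raise KeyError(f"unknown compartment {compartment!r}")
        return self._scores.get(protein, {}).get(compartment, 0.0)

    def cost(self, protein: str, compartment: str, base: float = math.e) -> float:
        return localization_cost(self, protein, compartment, base=base)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein": p, **{c: self.score(p, c) for c in self.compartments}}
            for p in sorted(self._scores)
        ]
        return pd.DataFrame(rows, columns=["protein", *self.compartments])


def localization_cost(
    table: LocalizationTable, protein: str, compartment: str, base: float = math.e
) -> float:
    """Additive localization cost ``-log(score)``; 0 maps to ``+inf``, 1 to 0.

    The log base only rescales all costs by a constant factor and therefore
    never changes any cost-minimizing assignment; natural log is the default.
    """
    s = table.score(protein, compartment)
    if s == 0.0:
        return math.inf
    return -math.log(s) / math.log(base)


def read_localization(path) -> LocalizationTable:
    """Read a localization TSV into a :class:`LocalizationTable`.

    Two dialects are accepted, detected from the header (or column count if
    headerless):

    * already aggregated: ``protein  extmem  cytosol  nucleus`` — 4 columns;
    * ComPPI-style: ``protein  extracellular  membrane  cytosol  nucleus
      [mitochondria  secretory]`` — ExtMem is taken as the maximum of the
      extracellular-fluid and cell-membrane scores (a protein reachable in
      either is a plausible signal origin).

    Scores must lie in ``[0, 1]``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    # header detection: second cell of first row non-numeric -> header row
    first = df.iloc[0]
    try:
        float(first[1])
        header = None
    except (TypeError, ValueError):
        header = [str(x).strip().lower() for x in first]
        df = df.iloc[1:].reset_index(drop=True)

    ncol = df.shape[1]
    if header is not None:
        cols = header
    elif ncol == 4:
        cols = ["protein", "extmem", "cytosol", "nucleus"]
    elif ncol >= 5:
        cols = ["protein", "extracellular", "membrane", "cytosol", "nucleus", "mitochondria", "secretory"][:ncol]
    else:
        raise ValueError(f"{path}: expected >= 4 columns, got {ncol}")
    df.columns = cols[: df.shape[1]]

    aliases = {
        "ext": "extmem",
        "extmem": "extmem",
        "cyt": "cytosol",
        "cytosol": "cytosol",
        "nuc": "nucleus",
        "nucleus": "nucleus",
        "extracellular": "extracellular",
        "membrane": "membrane",
        "mem": "membrane",
        "mitochondria": "mitochondria",
        "mito": "mitochondria",
        "secretory": "secretory",
        "secr": "secretory",
    }
    canon = {}
    for c in df.columns[1:]:
        key = aliases.get(str(c).strip().lower())
        if key is not None:
            canon[key] = pd.to_numeric(df[c])

    compartments = [EXTMEM, CYTOSOL, NUCLEUS]
    out: dict[str, dict[str, float]] = {}
    extras = [k for k in (MITOCHONDRIA, SECRETORY) if aliases.get(k.lower()) in canon or k.lower() in canon]
    for name in extras:
        compartments.append(name)
    proteins = df.iloc[:, 0].astype(str)
    for i, protein in enumerate(proteins):
        row: dict[str, float] = {}
        if "extmem" in canon:
            row[EXTMEM] = float(canon["extmem"].iloc[i])
        else:
            row[EXTMEM] = max(float(canon["extracellular"].iloc[i]), float(canon["membrane"].iloc[i]))
        row[CYTOSOL] = float(canon["cytosol"].iloc[i])
        row[NUCLEUS] = float(canon["nucleus"].iloc[i])
        if "mitochondria" in canon:
            row[MITOCHONDRIA] = float(canon["mitochondria"].iloc[i])
        if "secretory" in canon:
            row[SECRETORY] = float(canon["secretory"].iloc[i])
        out[protein] = row
    return LocalizationTable(out, compartments=tuple(compartments))


def filter_interactome(g: Interactome, table: LocalizationTable | None = None) -> Interactome:
    """Keep exactly the edges with a positive interaction score.

    The interaction score is read from the edge itself, falling back to
    ``table.edge_scores``; a missing score counts as zero.  Nodes left
    isolated by the filter are dropped.  The operation is idempotent.
    """
    out = Interactome()
    for u, v, d in g.graph.edges(data=True):
        score = d.get("interaction_score")
        if score is None and table is not None:
            score = table.edge_scores.get((u, v))
        if score is not None and score > 0.0:
            out.graph.add_edge(u, v, **d)
    return out
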