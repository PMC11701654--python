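"""Cell-type ontology queries and expression roll-up.

The Cell Ontology relates cell-type terms by ``is_a`` edges (child → parent),
e.g. "B cell" is a descendant of "lymphocyte". Because different datasets
annotate cells at different granularity, per-term summaries are *rolled up*:
the value reported for a term sums over cells labeled with that term or any
of its descendants. On a true DAG (multiple parents), set semantics apply —
a cell contributes at most once to each ancestor, regardless of how many
paths connect its label to that ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OntologyGraph:
    """Directed acyclic graph over cell-type CURIEs; edges point child → parent."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def descendants(self, term: str) -> set[str]:
        """The term itself plus every term below it (reflexive-transitive)."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term: {term!r}")
        # edges run child -> parent, so terms below = nodes with a path TO term
        return {term} | nx.ancestors(self.graph, term)

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus every term above it."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term: {term!r}")
        return {term} | nx.descendants(self.graph, term)

    def is_descendant(self, a: str, b: str) -> bool:
        """True iff ``a`` is ``b`` or lies below ``b``."""
        return a in self.descendants(b)


def rollup(
    cell_assignments: Sequence[str] | pd.Series,
    quantities: Mapping[str, Sequence[float]] | Sequence[float],
    graph: OntologyGraph,
) -> pd.DataFrame:
    """Roll per-cell quantities up the ontology.

    For every term with at least one labeled cell at or below it, sums each
    quantity over the *set* of cells labeled with any member of
    ``descendants(term)`` and counts those cells. Terms with no labeled cells
    anywhere below are absent from the output.

    Parameters
    ----------
    cell_assignments
        One ontology term per cell.
    quantities
        A single per-cell vector, or a mapping of named per-cell vectors.
    graph
        The cell-type ontology.

    Returns
    -------
    DataFrame indexed by term with one column per quantity plus ``n_cells``.
    """
    labels = pd.Series(list(cell_assignments), dtype=object)
    unknown = sorted(set(labels) - graph.nodes)
    if unknown:
        raise KeyError(f"cells labeled with unknown ontology terms: {unknown}")

    if not isinstance(quantities, Mapping):
        quantities = {"value": quantities}
    qframe = pd.DataFrame(
        {name: np.asarray(vals, dtype=float) for name, vals in quantities.items()}
    )
    if len(qframe) != len(labels):
        raise ValueError("quantities not aligned to cell assignments")

    # Each cell has exactly one label, so summing per label first and then
    # attributing the label's totals to each of its ancestors counts every
    # cell once per ancestor even when the DAG has multiple parents.
    per_label = qframe.groupby(labels, sort=False).sum()
    per_label["n_cells"] = labels.groupby(labels, sort=False).size()

    rows: dict[str, np.ndarray] = {}
    for label, values in per_label.iterrows():
        for anc in graph.ancestors(str(label)):
            if anc in rows:
                rows[anc] = rows[anc] + values.to_numpy()
            else:
                rows[anc] = values.to_numpy().copy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=per_label.columns)
    out["n_cells"] = out["n_cells"].astype(int)
    out.index.name = "term"
    return out.sort_index()


def prune_colinear(terms: Iterable[str], graph: OntologyGraph) -> set[str]:
    """Drop the more basal member of every ancestor/descendant pair.

    When two terms lie on one ontology path they describe overlapping cell
    populations; keeping only the more specific (descendant) term leaves an
    antichain of mutually incomparable terms.
    """
    terms = set(terms)
    missing = terms - graph.nodes
    if missing:
        raise KeyError(f"terms not in ontology: {sorted(missing)}")
    keep = set()
    for t in terms:
        strict_below = graph.descendants(t) - {t}
        if not (strict_below & terms):
            keep.add(t)
    return keep
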