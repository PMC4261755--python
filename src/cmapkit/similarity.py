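"""Graph-similarity metric and family sorting over contact maps.

The metric works on an adjacency-matrix abstraction of the contact map.  Its
"nodes" are the matrix rows, built bottom-up: every state node is a row, and
a component is a row only if it has no states (molecules always have at least
one component, so every molecule is represented).  Its "edges" are the
binding-interaction edges.

For two models *G* and *H* four quantities are computed:

* ``nodes_shared`` — number of rows with identical identifiers in both,
* ``edges_shared`` — number of edges with identical identifiers in both,
* ``node_fraction`` — nodes_shared / rows of the smaller graph,
* ``edge_fraction`` — edges_shared / edges of the smaller graph,

so a subgraph scores fractions of 1 against any supergraph regardless of the
size difference.  The combined absolute score is

    score(G, H) = nodes_shared * node_fraction + edges_shared * edge_fraction

which rewards both a large common structure and near-containment.  Families
are ordered by the score against the *most complete* member, the one with the
greatest rows + edges count (model families tend to grow as they develop, so
the most complete member is the best reference).

Fractions are kept in [0, 1]; when the smaller graph has no rows (or edges)
the corresponding fraction is defined as 0 — the paired count is 0 too, so
the score is unaffected and no division is undefined.  Identifier equality is
the only matching mechanism; synonymous names are different elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cmapkit.contact_map import (
    ContactMap,
    edge_ids,
    matrix_row_ids,
    unstructured_id,
)

__all__ = [
    "AdjacencyMatrix",
    "SimilarityMatrices",
    "FamilyOrdering",
    "adjacency_matrix",
    "matrix_rows",
    "shared_counts",
    "shared_fractions",
    "absolute_similarity",
    "similarity_matrices",
    "most_complete",
    "sort_family",
]


@dataclass
class AdjacencyMatrix:
    """Boolean adjacency over the metric's rows; entry (i, j) is true when a
    binding edge joins the components owning rows i and j (the diagonal
    encodes homodimerization self-edges)."""

    row_ids: list[str]
    entries: np.ndarray  # (n, n) bool, symmetric


def matrix_rows(cmap: ContactMap) -> list[str]:
    """The metric's node set: state ids plus stateless-component ids, sorted."""
    return matrix_row_ids(cmap)


def adjacency_matrix(cmap: ContactMap) -> AdjacencyMatrix:
    rows = matrix_row_ids(cmap)
    index: dict[tuple[str, str, int], list[int]] = {}
    for i, rid in enumerate(rows):
        base = rid.split("~", 1)[0]  # strip state suffix -> component id
        mol, rest = base.split(".", 1)
        comp, occ = rest.split("#", 1)
        index.setdefault((mol, comp, int(occ)), []).append(i)
    entries = np.zeros((len(rows), len(rows)), dtype=bool)
    for edge in cmap.edges:
        (m1, c1, k1, _s1), (m2, c2, k2, _s2) = edge.endpoints
        for i in index.get((m1, c1, k1), ()):
            for j in index.get((m2, c2, k2), ()):
                entries[i, j] = True
                entries[j, i] = True
    return AdjacencyMatrix(row_ids=rows, entries=entries)


# ---------------------------------------------------------------------------
# pairwise metric


def _metric_edges(cmap: ContactMap, include_unstructured: bool) -> set[str]:
    ids = edge_ids(cmap)
    if include_unstructured:
        ids |= {unstructured_id(mol, kind) for kind, mol in cmap.unstructured_nodes}
    return ids


def shared_counts(
    a: ContactMap, b: ContactMap, *, include_unstructured: bool = False
) -> tuple[int, int]:
    """(nodes shared, edges shared) by identifier equality; symmetric.

    ``include_unstructured`` also counts synthesis/degradation markers in the
    edge totals; by default they are excluded (they are not binding
    interactions).
    """
    nodes = len(set(matrix_row_ids(a)) & set(matrix_row_ids(b)))
    edges = len(_metric_edges(a, include_unstructured) & _metric_edges(b, include_unstructured))
    return nodes, edges


def shared_fractions(
    a: ContactMap, b: ContactMap, *, include_unstructured: bool = False
) -> tuple[float, float]:
    """Fractions of the smaller graph contained in the larger, per kind.

    "Smaller" is judged independently for nodes and edges.  A subgraph scores
    (1.0, 1.0) against any supergraph.  If the smaller graph has no rows (or
    edges) that fraction is 0 by convention.
    """
    nodes_shared, edges_shared = shared_counts(a, b, include_unstructured=include_unstructured)
    n_min = min(len(matrix_row_ids(a)), len(matrix_row_ids(b)))
    e_min = min(
        len(_metric_edges(a, include_unstructured)), len(_metric_edges(b, include_unstructured))
    )
    node_fraction = nodes_shared / n_min if n_min else 0.0
    edge_fraction = edges_shared / e_min if e_min else 0.0
    return node_fraction, edge_fraction


def absolute_similarity(
    a: ContactMap, b: ContactMap, *, include_unstructured: bool = False
) -> float:
    """Combined score: nodes_shared*node_fraction + edges_shared*edge_fraction.

    Symmetric; 0 iff nothing is shared; equals rows + edges for a self
    comparison (fractions are both 1).
    """
    nodes_shared, edges_shared = shared_counts(a, b, include_unstructured=include_unstructured)
    node_fraction, edge_fraction = shared_fractions(
        a, b, include_unstructured=include_unstructured
    )
    return nodes_shared * node_fraction + edges_shared * edge_fraction


# ---------------------------------------------------------------------------
# family-level


@dataclass
class SimilarityMatrices:
    """The four pairwise matrices plus the combined absolute score."""

    model_names: list[str]
    shared_node_count: np.ndarray  # (n, n) int
    shared_edge_count: np.ndarray  # (n, n) int
    node_fraction: np.ndarray  # (n, n) float in [0, 1]
    edge_fraction: np.ndarray  # (n, n) float in [0, 1]
    absolute: np.ndarray  # (n, n) float

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "shared_node_count": self.shared_node_count,
            "shared_edge_count": self.shared_edge_count,
            "node_fraction": self.node_fraction,
            "edge_fraction": self.edge_fraction,
            "absolute": self.absolute,
        }


def similarity_matrices(
    family: list[ContactMap], *, include_unstructured: bool = False
) -> SimilarityMatrices:
    """Precompute all five matrices for every unordered pair in the family."""
    if not family:
        raise ValueError("similarity_matrices needs at least one model")
    n = len(family)
    node_c = np.zeros((n, n), dtype=int)
    edge_c = np.zeros((n, n), dtype=int)
    node_f = np.zeros((n, n), dtype=float)
    edge_f = np.zeros((n, n), dtype=float)
    absolute = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            ns, es = shared_counts(family[i], family[j], include_unstructured=include_unstructured)
            nf, ef = shared_fractions(
                family[i], family[j], include_unstructured=include_unstructured
            )
            node_c[i, j] = node_c[j, i] = ns
            edge_c[i, j] = edge_c[j, i] = es
            node_f[i, j] = node_f[j, i] = nf
            edge_f[i, j] = edge_f[j, i] = ef
            absolute[i, j] = absolute[j, i] = ns * nf + es * ef
    return SimilarityMatrices(
        model_names=[c.name for c in family],
        shared_node_count=node_c,
        shared_edge_count=edge_c,
        node_fraction=node_f,
        edge_fraction=edge_f,
        absolute=absolute,
    )


def most_complete(family: list[ContactMap], *, include_unstructured: bool = False) -> int:
    """Index of the most complete model: argmax of rows + edges, ties broken
    by model name ascending."""
    if not family:
        raise ValueError("most_complete needs at least one model")
    best = 0
    best_key = None
    for i, cmap in enumerate(family):
        size = len(matrix_row_ids(cmap)) + len(_metric_edges(cmap, include_unstructured))
        key = (-size, cmap.name)
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


@dataclass
class FamilyOrdering:
    """Row-wise display order: the most complete model first, the rest by
    descending similarity to it (name-ascending on ties)."""

    reference: int  # index into the input family
    order: list[int] = field(default_factory=list)  # permutation, order[0] == reference
    scores: list[float] = field(default_factory=list)  # score vs reference, aligned with order


def sort_family(
    family: list[ContactMap], *, include_unstructured: bool = False
) -> FamilyOrdering:
    ref = most_complete(family, include_unstructured=include_unstructured)
    scored = []
    for i, cmap in enumerate(family):
        if i == ref:
            continue
        s = absolute_similarity(family[ref], cmap, include_unstructured=include_unstructured)
        scored.append((-s, cmap.name, i, s))
    scored.sort()
    ref_score = absolute_similarity(family[ref], family[ref], include_unstructured=include_unstructured)
    return FamilyOrdering(
        reference=ref,
        order=[ref] + [i for _negs, _name, i, _s in scored],
        scores=[ref_score] + [s for _negs, _name, _i, s in scored],
    )
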