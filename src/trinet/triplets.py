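"""Heterogeneous-triangle (triplet) detection and pathway screening.

A triplet is a 3-clique of the integrative network containing exactly one
mRNA, one lncRNA and one miRNA — three RNAs every two of which were found
co-regulated by the per-target regressions.  Triangles are listed by edge
iteration with neighbor-set intersection, which is exact for size-3
cliques and linear in the number of triangles; no maximal-clique search
is involved.
"""

from __future__ import annotations

from collections import namedtuple

from .exceptions import ValidationError
from .genesets import GeneSet
from .network import RegulatoryGraph

#: One mRNA-lncRNA-miRNA cross-regulation unit; slots are typed by name.
Triplet = namedtuple("Triplet", ["mrna", "lncrna", "mirna"])

_SLOT_BY_TYPE = {"mRNA": "mrna", "lncRNA": "lncrna", "miRNA": "mirna"}


def find_heterogeneous_triangles(graph: RegulatoryGraph) -> list[Triplet]:
    """Every triangle whose three vertices cover all three RNA types.

    For each edge (u, v), the common neighbors N(u) & N(v) close a
    triangle; a total order on vertices (w > u, w > v) deduplicates the
    three rotations.  Triangles whose type multiset is not exactly
    {mRNA, lncRNA, miRNA} are discarded.  Output is sorted
    lexicographically by (mrna, lncrna, mirna).
    """
    types = graph.vertices()
    out = []
    for u, v, _r2 in graph.edges():
        common = graph.neighbors(u) & graph.neighbors(v)
        for w in common:
            if str(w) <= str(u) or str(w) <= str(v):
                continue
            tri_types = {types[u], types[v], types[w]}
            if len(tri_types) != 3:
                continue
            slots = {}
            for node in (u, v, w):
                slots[_SLOT_BY_TYPE[types[node]]] = node
            out.append(Triplet(**slots))
    out.sort()
    return out


def screen_by_pathway(triplets: list[Triplet], geneset: GeneSet) -> list[Triplet]:
    """Keep triplets whose mRNA belongs to the pathway gene set.

    Membership is case-insensitive (gene-set symbols are uppercased on
    load); input order is preserved.
    """
    members = {m.upper() for m in geneset.members}
    return [t for t in triplets if str(t.mrna).upper() in members]


def triplet_census(triplets: list[Triplet]) -> dict:
    """Distinct gene counts per slot, plus their sum."""
    mrnas = {t.mrna for t in triplets}
    lncrnas = {t.lncrna for t in triplets}
    mirnas = {t.mirna for t in triplets}
    return {
        "n_triplets": len(triplets),
        "distinct_mrna": len(mrnas),
        "distinct_lncrna": len(lncrnas),
        "distinct_mirna": len(mirnas),
        "distinct_total": len(mrnas) + len(lncrnas) + len(mirnas),
    }


def validate_triplet(t: Triplet, graph: RegulatoryGraph | None = None) -> None:
    """Check distinctness, and against a graph, typing and adjacency."""
    if len({t.mrna, t.lncrna, t.mirna}) != 3:
        raise ValidationError(f"triplet members must be distinct: {t}")
    if graph is not None:
        types = graph.vertices()
        for slot, typ in (("mrna", "mRNA"), ("lncrna", "lncRNA"),
                          ("mirna", "miRNA")):
            node = getattr(t, slot)
            if types.get(node) != typ:
                raise ValidationError(
                    f"{node} is not a {typ} vertex of the graph")
        for a, b in ((t.mrna, t.lncrna), (t.mrna, t.mirna),
                     (t.lncrna, t.mirna)):
            if not graph.has_edge(a, b):
                raise ValidationError(f"missing edge {a} -- {b}")
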