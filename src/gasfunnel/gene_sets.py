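"""Immune-gene set construction from the Gene Ontology (or a plain list).

The immune gene set is defined as every gene annotated to a term at or
below a configurable set of root GO terms — by default the immune-system
branch (immune system process, immune response, cytokine signaling,
interferon-gamma signaling, interleukin signaling and the JAK-STAT
cascade).  "Below" follows child-to-parent ``is_a`` edges of the ontology
DAG; ``part_of`` can optionally be included.

A plain newline-delimited gene list bypasses the ontology path entirely, so
the funnel is runnable without GO files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import obonet

from ._util import BadInputError

#: Immune-system branch roots used by default.
DEFAULT_GO_ROOTS = (
    "GO:0002376",  # immune system process
    "GO:0006955",  # immune response
    "GO:0019221",  # cytokine-mediated signaling
    "GO:0060333",  # interferon-gamma-mediated signaling
    "GO:0070102",  # interleukin-6-mediated signaling
    "GO:0007259",  # JAK-STAT cascade
)


@dataclass
class OntologyGraph:
    """An ontology DAG plus gene-to-term annotations.

    ``graph`` holds child -> parent edges restricted to the relations being
    followed; ``annotations`` maps a gene symbol/id to the set of terms it
    is directly annotated to.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]] = field(default_factory=dict)


def load_obo(path, relations: tuple[str, ...] = ("is_a",)) -> OntologyGraph:
    """Parse an OBO v1.2 ontology, keeping only the requested relations."""
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes(data=True))
    for child, parent, rel in multi.edges(keys=True):
        if rel in relations:
            g.add_edge(child, parent, relation=rel)
    return OntologyGraph(graph=g)


def load_gaf(ontology: OntologyGraph, path,
             evidence_include: set[str] | None = None) -> None:
    """Load GAF 2.x annotations into the ontology's gene->term map.

    Annotations to terms missing from the ontology graph are rejected (they
    indicate an ontology/annotation release mismatch).
    """
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise BadInputError(f"{path}:{ln}: expected >=7 GAF columns")
            symbol, term, evidence = fields[2], fields[4], fields[6]
            if evidence_include and evidence not in evidence_include:
                continue
            if term not in ontology.graph:
                raise BadInputError(
                    f"{path}:{ln}: annotation term {term} not in ontology")
            ontology.annotations.setdefault(symbol, set()).add(term)


def descendant_closure(ontology: OntologyGraph,
                       roots: list[str] | tuple[str, ...]) -> set[str]:
    """All terms at or below the roots (child->parent reachability).

    With edges pointing child -> parent, the terms below a root are exactly
    the nodes from which the root is reachable.
    """
    g = ontology.graph
    for root in roots:
        if root not in g:
            raise BadInputError(f"root term not in ontology: {root}")
    if not nx.is_directed_acyclic_graph(g):
        raise BadInputError("ontology graph contains a cycle")
    closure: set[str] = set(roots)
    for root in roots:
        closure |= nx.ancestors(g, root)
    return closure


def genes_for_terms(ontology: OntologyGraph, term_set: set[str]) -> set[str]:
    """All genes annotated to at least one term of the set."""
    return {gene for gene, terms in ontology.annotations.items()
            if terms & term_set}


def load_gene_list(path) -> set[str]:
    """Newline-delimited gene symbols/ids; blank lines and '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                genes.add(name)
    return genes


def immune_gene_set(gene_list_path=None, obo_path=None, gaf_path=None,
                    roots: tuple[str, ...] = DEFAULT_GO_ROOTS,
                    relations: tuple[str, ...] = ("is_a",)) -> set[str]:
    """Resolve the immune gene set from either input style."""
    if gene_list_path is not None:
        return load_gene_list(gene_list_path)
    if obo_path is None or gaf_path is None:
        raise BadInputError(
            "need either a gene list or an OBO ontology plus GAF annotations")
    ontology = load_obo(obo_path, relations=relations)
    load_gaf(ontology, gaf_path)
    return genes_for_terms(ontology, descendant_closure(ontology, roots))
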