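"""Ontology handling: OBO parsing, closures, true-path propagation, IC.

The class hierarchy is the ``is_a`` DAG of an OBO ontology (HPO, GO, or a
synthetic stand-in).  Everything downstream — annotation propagation, the
subclass indicator matrix used by the hierarchical classification layer,
and both information-content variants — is derived from this graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import obonet

__all__ = [
    "Ontology",
    "SubclassMatrix",
    "ICTable",
    "parse_obo",
    "closure",
    "propagate",
    "subclass_matrix",
    "conditional_ic",
    "marginal_ic",
]


class OntologyError(ValueError):
    """Structural problem with an ontology (cycle, unknown class, ...)."""


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG of ontology classes.

    ``graph`` holds one node per non-obsolete class and one child->parent
    edge per ``is_a`` assertion.  ``alt_ids`` maps secondary identifiers to
    their primary class id.
    """

    graph: nx.DiGraph
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise OntologyError(f"is_a hierarchy contains a cycle: {cyc}")

    @property
    def classes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        # roots have no parent, i.e. no outgoing child->parent edge
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, class_id: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if class_id in self.graph:
            return class_id
        return self.alt_ids.get(class_id, class_id)

    def parents(self, class_id: str) -> set[str]:
        self._check(class_id)
        return set(self.graph.successors(class_id))

    def children(self, class_id: str) -> set[str]:
        self._check(class_id)
        return set(self.graph.predecessors(class_id))

    def ancestors(self, class_id: str) -> set[str]:
        """Reflexive transitive is_a closure upwards."""
        self._check(class_id)
        return nx.descendants(self.graph, class_id) | {class_id}

    def descendants(self, class_id: str) -> set[str]:
        """Reflexive transitive is_a closure downwards."""
        self._check(class_id)
        return nx.ancestors(self.graph, class_id) | {class_id}

    def _check(self, class_id: str) -> None:
        if class_id not in self.graph:
            raise OntologyError(f"unknown ontology class: {class_id!r}")

    @classmethod
    def from_edges(
        cls, classes: Iterable[str], is_a_edges: Iterable[tuple[str, str]]
    ) -> "Ontology":
        """Build directly from a class list and (child, parent) pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(classes)
        for child, parent in is_a_edges:
            for end in (child, parent):
                if end not in g:
                    raise OntologyError(f"edge endpoint {end!r} not in classes")
            g.add_edge(child, parent)
        return cls(graph=g)


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2/1.4 file into an :class:`Ontology`.

    Obsolete terms are dropped.  ``alt_id`` values are recorded so they can
    be resolved to their primary id; a ``replaced_by`` tag on an obsolete
    term is followed once.  Only ``is_a`` edges define the hierarchy; any
    other relationship (e.g. ``part_of``) is ignored with a warning.
    """
    raw = obonet.read_obo(path, ignore_obsolete=False)
    g = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    replaced: dict[str, str] = {}
    dropped_relations: set[str] = set()

    for node, data in raw.nodes(data=True):
        if data.get("is_obsolete") == "true" or data.get("is_obsolete") is True:
            rb = data.get("replaced_by")
            if rb:
                replaced[node] = rb[0] if isinstance(rb, list) else rb
            continue
        g.add_node(node, name=data.get("name"))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    for node, data in raw.nodes(data=True):
        if node not in g:
            continue
        for parent in data.get("is_a", []):
            if parent in g:
                g.add_edge(node, parent)
        for rel in data.get("relationship", []):
            dropped_relations.add(rel.split(" ")[0])

    # follow replaced_by once: an alt route into the merged survivor
    for old, new in replaced.items():
        if new in g:
            alt_ids.setdefault(old, new)

    if dropped_relations:
        warnings.warn(
            "ignoring non-is_a relationships: " + ", ".join(sorted(dropped_relations)),
            stacklevel=2,
        )
    return Ontology(graph=g, alt_ids=alt_ids)


def closure(
    ont: Ontology, class_id: str, direction: Literal["ancestors", "descendants"]
) -> set[str]:
    """Reflexive transitive closure of ``class_id`` along is_a edges."""
    if direction == "ancestors":
        return ont.ancestors(class_id)
    if direction == "descendants":
        return ont.descendants(class_id)
    raise ValueError(f"direction must be 'ancestors' or 'descendants', got {direction!r}")


def propagate(ont: Ontology, annots, on_unknown: Literal["drop", "error"] = "drop"):
    """Close every gene's annotation set under ancestors (true path rule).

    Idempotent; unknown classes are dropped with a warning by default.
    Returns a new :class:`~hierpheno.data.AnnotationSet` flagged propagated.
    """
    from .data import AnnotationSet  # local import to avoid a cycle

    # memoised ancestor closures: annotation corpora reuse classes heavily
    cache: dict[str, set[str]] = {}
    unknown: set[str] = set()
    assignments: dict[str, set[str]] = {}
    for gene in annots.gene_ids:
        closed: set[str] = set()
        for c in annots.assignments.get(gene, ()):
            c = ont.resolve(c)
            if c not in ont:
                if on_unknown == "error":
                    raise OntologyError(f"annotated class {c!r} not in ontology")
                unknown.add(c)
                continue
            if c not in cache:
                cache[c] = ont.ancestors(c)
            closed |= cache[c]
        assignments[gene] = closed
    if unknown:
        warnings.warn(
            f"dropped {len(unknown)} annotated classes missing from the ontology",
            stacklevel=2,
        )
    return AnnotationSet(
        gene_ids=list(annots.gene_ids),
        assignments=assignments,
        propagated=True,
        ontology_id=annots.ontology_id,
    )


@dataclass(frozen=True)
class SubclassMatrix:
    """Reflexive subclass indicator over an ordered class list.

    ``matrix[i, j] == 1`` iff ``class_order[j]`` is a (reflexive) subclass
    of ``class_order[i]``.  This is the binary mask consumed by the
    hierarchical classification layer: row *i* selects the scores of all
    descendants of class *i*.
    """

    class_order: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.class_order)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape does not match class_order length")

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.class_order)}


def subclass_matrix(ont: Ontology, class_order) -> SubclassMatrix:
    """Build the k×k reflexive subclass indicator for ``class_order``."""
    order = list(class_order)
    if len(set(order)) != len(order):
        raise ValueError("class_order contains duplicate ids")
    idx = {c: i for i, c in enumerate(order)}
    k = len(order)
    mat = np.zeros((k, k), dtype=np.int8)
    for i, c in enumerate(order):
        for d in ont.descendants(c):
            j = idx.get(d)
            if j is not None:
                mat[i, j] = 1
    return SubclassMatrix(class_order=tuple(order), matrix=mat)


@dataclass(frozen=True)
class ICTable:
    """Per-class information content.

    ``mode='conditional'`` is the parent-conditional IC used by the Smin
    semantic-distance metric: IC(c) = -log Pr(c | parents(c)).
    ``mode='marginal'`` is the corpus-frequency IC used by Resnik
    similarity: IC(c) = -log p(c).
    """

    mode: Literal["conditional", "marginal"]
    values: Mapping[str, float]
    corpus_size: int
    log_base: float = 2.0
    # IC handed to classes never seen in the corpus (marginal mode)
    fallback: float = 0.0

    def __getitem__(self, class_id: str) -> float:
        v = self.values.get(class_id)
        return self.fallback if v is None else v

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.values


def _annotation_counts(annots) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    for gene in annots.gene_ids:
        for c in annots.assignments.get(gene, ()):
            counts[c] = counts.get(c, 0) + 1
    return counts, len(annots.gene_ids)


def conditional_ic(annots, ont: Ontology, log_base: float = 2.0) -> ICTable:
    """Parent-conditional information content from a propagated corpus.

    For class c with parent set P(c), Pr(c|P(c)) is the number of genes
    annotated with c over the number of genes annotated with *every* parent
    of c; roots use the corpus size as denominator.  Classes whose
    denominator is zero get IC 0 (they cannot be conditioned on), keeping
    Smin finite.
    """
    if not annots.propagated:
        raise ValueError("conditional_ic requires a propagated AnnotationSet")
    if not annots.gene_ids:
        raise ValueError("empty annotation corpus")
    counts, n = _annotation_counts(annots)
    # invert: class -> set of gene indices, so multi-parent denominators
    # (genes carrying ALL parents) are set intersections
    genes_with: dict[str, set[int]] = {}
    for gi, gene in enumerate(annots.gene_ids):
        for c in annots.assignments.get(gene, ()):
            genes_with.setdefault(c, set()).add(gi)
    scale = 1.0 / np.log(log_base)
    values: dict[str, float] = {}
    # cover every ontology class: zero-probability classes get IC 0 so
    # downstream Smin stays finite and fully defined
    for c in ont.classes:
        n_c = counts.get(c, 0)
        if n_c == 0:
            values[c] = 0.0
            continue
        parents = ont.parents(c)
        if parents:
            carriers: set[int] | None = None
            for p in parents:
                pg = genes_with.get(p, set())
                carriers = pg if carriers is None else carriers & pg
            denom = len(carriers or ())
        else:
            denom = n
        if denom == 0 or n_c == 0:
            values[c] = 0.0
        else:
            p_cond = min(n_c / denom, 1.0)
            values[c] = float(-np.log(p_cond) * scale)
    return ICTable(mode="conditional", values=values, corpus_size=n, log_base=log_base)


def marginal_ic(annots, log_base: float = 2.0) -> ICTable:
    """Corpus-marginal information content: IC(c) = -log(n_c / n).

    Classes annotated to every gene (the root, after propagation) get IC 0.
    A class absent from the corpus has undefined IC; lookups on the returned
    table fall back to the maximum observed IC so Resnik stays finite.
    """
    if not annots.propagated:
        raise ValueError("marginal_ic requires a propagated AnnotationSet")
    if not annots.gene_ids:
        raise ValueError("empty annotation corpus")
    counts, n = _annotation_counts(annots)
    scale = 1.0 / np.log(log_base)
    values = {c: float(-np.log(n_c / n) * scale) for c, n_c in counts.items()}
    fallback = max(values.values(), default=0.0)
    return ICTable(
        mode="marginal",
        values=values,
        corpus_size=n,
        log_base=log_base,
        fallback=fallback,
    )
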