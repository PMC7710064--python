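"""Synthetic ontologies, annotation corpora and planted-rule datasets.

Every other module is testable without downloads: :func:`gen_ontology`
draws a single-rooted is_a DAG, :func:`gen_planted` builds a gene corpus
whose phenotype labels are a known boolean function of GO features (each
leaf phenotype fires iff the gene carries a planted set of GO classes),
and :func:`gen_interaction_graph` plants phenotype-module cliques in a
background interaction network.

The planted construction mirrors, at desk scale, how clinical annotation
corpora behave: specific classes are annotated directly and propagate to
ancestors, class frequency decays with depth, and the expression block
carries a per-phenotype mean shift so that expression features are
informative about labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnnotationSet, FeatureMatrix, build_features
from .ontology import Ontology, propagate

__all__ = [
    "PlantedDataset",
    "gen_ontology",
    "gen_planted",
    "gen_interaction_graph",
    "write_obo",
    "write_interactions",
]


def gen_ontology(
    n_classes: int, max_parents: int = 2, seed: int = 0, prefix: str = "HP"
) -> Ontology:
    """Random single-rooted DAG: class i draws 1..max_parents parents among
    classes 0..i-1 (class 0 is the root), so the graph is acyclic by
    construction."""
    if n_classes < 1 or max_parents < 1:
        raise ValueError("n_classes and max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}:{i:07d}" for i in range(n_classes)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_classes):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        edges.extend((ids[i], ids[int(p)]) for p in parents)
    return Ontology.from_edges(ids, edges)


@dataclass
class PlantedDataset:
    """A synthetic corpus with a known GO→phenotype generating rule."""

    go_ontology: Ontology
    hpo_ontology: Ontology
    go_annotations: AnnotationSet  # propagated
    features: FeatureMatrix
    labels: AnnotationSet  # propagated phenotype annotations
    direct_labels: AnnotationSet  # leaf labels before ancestor closure
    expression: pd.DataFrame | None
    rules: dict[str, frozenset[str]]
    noise_rate: float
    seed: int
    gene_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.features.gene_ids)


def gen_planted(
    go_ont: Ontology | None = None,
    hpo_ont: Ontology | None = None,
    n_genes: int = 300,
    rule_size: int = 2,
    noise_rate: float = 0.1,
    expression_tissues: int = 53,
    seed: int = 0,
    rule_carry_prob: float = 0.1,
    background_go: int = 5,
    expression_shift: float = 1.0,
) -> PlantedDataset:
    """Generate a planted-rule gene corpus.

    Each leaf phenotype class receives a random rule: a set of
    ``rule_size`` non-root GO classes.  Each gene carries each rule's GO
    classes with probability ``rule_carry_prob`` plus ``background_go``
    random direct GO classes; GO annotations are then propagated into
    binary features.  A gene is labeled with a leaf phenotype iff its
    propagated GO set contains the whole rule; direct labels are then
    flipped independently with probability ``noise_rate`` and closed under
    ancestors.  The expression block is standard normal per (gene, tissue)
    plus a fixed random direction of length ``expression_shift`` per
    phenotype the gene is labeled with.
    """
    rng = np.random.default_rng(seed)
    if go_ont is None:
        go_ont = gen_ontology(200, max_parents=2, seed=seed + 1, prefix="GO")
    if hpo_ont is None:
        hpo_ont = gen_ontology(100, max_parents=2, seed=seed + 2, prefix="HP")

    go_classes = sorted(go_ont.classes)
    go_nonroot = sorted(set(go_classes) - go_ont.roots)
    if rule_size > len(go_nonroot):
        raise ValueError("rule_size exceeds the number of non-root GO classes")
    leaves = sorted(c for c in hpo_ont.classes if not hpo_ont.children(c) - {c})
    rules: dict[str, frozenset[str]] = {
        p: frozenset(rng.choice(go_nonroot, size=rule_size, replace=False))
        for p in leaves
    }

    genes = [f"g{i:05d}" for i in range(n_genes)]
    direct_go: dict[str, set[str]] = {}
    for g in genes:
        s: set[str] = set()
        for p in leaves:
            if rng.random() < rule_carry_prob:
                s |= rules[p]
        extra = rng.choice(go_nonroot, size=background_go, replace=False)
        s |= set(extra)
        direct_go[g] = s
    go_annots = propagate(
        go_ont,
        AnnotationSet(
            gene_ids=genes, assignments=direct_go, ontology_id="GO"
        ),
    )

    # deterministic labels from propagated GO sets, then independent flips
    direct: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        carried = go_annots.assignments[g]
        for p in leaves:
            labeled = rules[p] <= carried
            if noise_rate > 0 and rng.random() < noise_rate:
                labeled = not labeled
            if labeled:
                direct[g].add(p)
    direct_labels = AnnotationSet(
        gene_ids=genes, assignments=direct, ontology_id="HP"
    )
    labels = propagate(hpo_ont, direct_labels)

    expression = None
    if expression_tissues > 0:
        shift_dirs = {}
        for p in leaves:
            v = rng.normal(size=expression_tissues)
            shift_dirs[p] = v / np.linalg.norm(v) * expression_shift
        mat = rng.normal(size=(n_genes, expression_tissues))
        for i, g in enumerate(genes):
            for p in direct[g]:
                mat[i] += shift_dirs[p]
        expression = pd.DataFrame(
            mat,
            index=pd.Index(genes, name="gene_id"),
            columns=[f"tissue_{t}" for t in range(expression_tissues)],
        )

    features = build_features(go_annots, vocab=go_classes, expression=expression)
    return PlantedDataset(
        go_ontology=go_ont,
        hpo_ontology=hpo_ont,
        go_annotations=go_annots,
        features=features,
        labels=labels,
        direct_labels=direct_labels,
        expression=expression,
        rules=rules,
        noise_rate=noise_rate,
        seed=seed,
    )


def gen_interaction_graph(
    known_sets: dict[str, set[str]],
    n_genes: int,
    clique_density: float = 1.0,
    background_density: float = 0.0,
    seed: int = 0,
    gene_prefix: str = "g",
) -> list[tuple[str, str]]:
    """Undirected edge list with planted phenotype-module cliques.

    Pairs within a known gene set connect with probability
    ``clique_density``; every other pair with ``background_density``.
    """
    for d in (clique_density, background_density):
        if not 0.0 <= d <= 1.0:
            raise ValueError("densities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    for s in known_sets.values():
        missing = s - gene_set
        if missing:
            raise ValueError(f"known genes outside the universe: {sorted(missing)[:5]}")
    module_pairs: set[tuple[str, str]] = set()
    for s in known_sets.values():
        members = sorted(s)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                module_pairs.add((members[i], members[j]))
    edges: set[tuple[str, str]] = set()
    for pair in module_pairs:
        if rng.random() < clique_density:
            edges.add(pair)
    if background_density > 0:
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                pair = (genes[i], genes[j])
                if pair in module_pairs:
                    continue
                if rng.random() < background_density:
                    edges.add(pair)
    return sorted(edges)


def write_obo(ont: Ontology, path, ontology_name: str = "synthetic") -> None:
    """Write the ontology as a minimal OBO 1.4 flat file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for c in sorted(ont.classes):
            fh.write("[Term]\n")
            fh.write(f"id: {c}\n")
            name = ont.graph.nodes[c].get("name") or c.replace(":", " ")
            fh.write(f"name: {name}\n")
            for parent in sorted(ont.parents(c)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def write_interactions(edges, path, score: float = 0.9) -> None:
    """Write an edge list as a 3-column (gene_a, gene_b, score) TSV."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\t{score}\n")
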