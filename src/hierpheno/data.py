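"""Annotation, expression and association tables; features; gene splits.

Readers are column-map driven so the same code handles the slightly
different dialects of HPO ``genes_to_phenotype`` releases, plain
two-column gene/class TSVs and GAF 2.x files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.UniProt import GOA

__all__ = [
    "AnnotationSet",
    "FeatureMatrix",
    "SplitSpec",
    "EXPERIMENTAL_EVIDENCE",
    "read_gene_phenotypes",
    "read_go_annotations",
    "read_expression",
    "select_classes",
    "build_features",
    "split_by_gene",
]

#: GO evidence codes treated as experimental / curated
EXPERIMENTAL_EVIDENCE = (
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
    "TAS", "IC", "HTP", "HDA", "HMP", "HGI", "HEP",
)


class FormatError(ValueError):
    """Malformed input table."""


@dataclass
class AnnotationSet:
    """gene -> set of ontology class ids.

    ``propagated`` records whether every gene's set is closed under
    ancestors (the true path rule); metrics and IC computations require
    propagated sets.
    """

    gene_ids: list[str]
    assignments: dict[str, set[str]]
    propagated: bool = False
    ontology_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        extra = set(self.assignments) - set(self.gene_ids)
        if extra:
            raise ValueError(f"assignments for unknown genes: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def classes(self) -> set[str]:
        out: set[str] = set()
        for s in self.assignments.values():
            out |= s
        return out

    def subset(self, genes: Sequence[str]) -> "AnnotationSet":
        genes = list(genes)
        return AnnotationSet(
            gene_ids=genes,
            assignments={g: set(self.assignments.get(g, set())) for g in genes},
            propagated=self.propagated,
            ontology_id=self.ontology_id,
        )

    def restrict_classes(self, keep: Iterable[str]) -> "AnnotationSet":
        keep = set(keep)
        return AnnotationSet(
            gene_ids=list(self.gene_ids),
            assignments={g: s & keep for g, s in self.assignments.items()},
            propagated=self.propagated,
            ontology_id=self.ontology_id,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, c)
            for g in self.gene_ids
            for c in sorted(self.assignments.get(g, ()))
        ]
        return pd.DataFrame(rows, columns=["gene_id", "class_id"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FeatureMatrix:
    """genes × (binary GO features ⊕ normalized expression features)."""

    gene_ids: list[str]
    go_vocab: list[str]
    go_block: np.ndarray
    expr_block: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.go_block.shape != (n, len(self.go_vocab)):
            raise ValueError("go_block shape mismatch")
        if self.expr_block is not None and self.expr_block.shape[0] != n:
            raise ValueError("expr_block row count mismatch")

    @property
    def n_tissues(self) -> int:
        return 0 if self.expr_block is None else self.expr_block.shape[1]

    def dense(self) -> np.ndarray:
        """Concatenated feature array (GO block then expression block)."""
        if self.expr_block is None:
            return self.go_block.astype(np.float64)
        return np.hstack([self.go_block.astype(np.float64), self.expr_block])


@dataclass
class SplitSpec:
    """Gene-level train/valid/test partitions, one triple per fold."""

    folds: list[dict[str, list[str]]]
    seed: int

    @property
    def fold_count(self) -> int:
        return len(self.folds)

    def __getitem__(self, i: int) -> dict[str, list[str]]:
        return self.folds[i]


def read_gene_phenotypes(
    path,
    gene_col: str | int = "gene_id",
    class_col: str | int = "hpo_id",
    sep: str = "\t",
    ontology_id: str = "HP",
) -> AnnotationSet:
    """Read a gene→phenotype TSV into an unpropagated annotation set.

    Columns are selected by name (or position for headerless files);
    duplicate (gene, class) rows are collapsed.
    """
    header = None if isinstance(gene_col, int) else 0
    df = pd.read_csv(path, sep=sep, header=header, dtype=str, comment="#")
    for col in (gene_col, class_col):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    df = df[[gene_col, class_col]].dropna().drop_duplicates()
    genes: list[str] = []
    assignments: dict[str, set[str]] = {}
    for g, c in df.itertuples(index=False):
        if g not in assignments:
            genes.append(g)
            assignments[g] = set()
        assignments[g].add(c)
    return AnnotationSet(
        gene_ids=genes, assignments=assignments, ontology_id=ontology_id
    )


def read_go_annotations(
    path,
    format: str = "tsv",
    evidence_filter: Sequence[str] | None = None,
    gene_col: str | int = "gene_id",
    class_col: str | int = "go_id",
) -> AnnotationSet:
    """Read GO annotations from a GAF 2.x file or a two-column TSV.

    ``evidence_filter`` keeps only rows whose evidence code is listed
    (e.g. :data:`EXPERIMENTAL_EVIDENCE`); GAF rows with a NOT qualifier
    are always dropped.  The plain TSV dialect has no evidence column and
    ignores the filter.
    """
    allowed = set(evidence_filter) if evidence_filter is not None else None
    genes: list[str] = []
    assignments: dict[str, set[str]] = {}

    def add(g: str, c: str) -> None:
        if g not in assignments:
            genes.append(g)
            assignments[g] = set()
        assignments[g].add(c)

    if format == "gaf":
        with open(path) as handle:
            for rec in GOA.gafiterator(handle):
                if any(q.startswith("NOT") for q in rec["Qualifier"]):
                    continue
                if allowed is not None and rec["Evidence"] not in allowed:
                    continue
                add(rec["DB_Object_ID"], rec["GO_ID"])
    elif format == "tsv":
        annots = read_gene_phenotypes(
            path, gene_col=gene_col, class_col=class_col, ontology_id="GO"
        )
        return annots
    else:
        raise ValueError(f"unknown annotation format {format!r} (use 'gaf' or 'tsv')")

    return AnnotationSet(gene_ids=genes, assignments=assignments, ontology_id="GO")


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Read a gene × tissue expression TSV.

    First column is the gene id; the remaining columns are tissues.
    Non-numeric cells become NaN (zero-filled later, at feature-building
    time).  A duplicated gene id keeps its last row, with a warning.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        warnings.warn(
            f"duplicated gene ids in expression table (last row wins): {dups[:5]}",
            stacklevel=2,
        )
        df = df[~df.index.duplicated(keep="last")]
    return df


def select_classes(
    annots: AnnotationSet,
    min_genes: int = 10,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Predictable classes: annotated to at least ``min_genes`` genes.

    Requires a propagated corpus (counts follow the true path rule).
    Ontology roots should be passed via ``exclude``; the returned order is
    lexicographic, hence deterministic.
    """
    if not annots.propagated:
        raise ValueError("select_classes requires propagated annotations")
    counts: dict[str, int] = {}
    for s in annots.assignments.values():
        for c in s:
            counts[c] = counts.get(c, 0) + 1
    excluded = set(exclude)
    return sorted(c for c, n in counts.items() if n >= min_genes and c not in excluded)


def build_features(
    go_annots: AnnotationSet,
    vocab: Sequence[str],
    expression: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Binary GO block (vocab order) plus per-gene z-scored expression.

    The vocabulary is fixed from training data; GO classes outside it are
    ignored.  Expression rows are z-scored per gene (constant rows become
    all zeros) and missing cells set to 0; genes without an expression
    record get an all-zero expression row.
    """
    vocab = list(vocab)
    if not vocab:
        raise ValueError("empty GO feature vocabulary")
    if not go_annots.propagated:
        raise ValueError("build_features requires propagated GO annotations")
    idx = {c: j for j, c in enumerate(vocab)}
    n = len(go_annots.gene_ids)
    go_block = np.zeros((n, len(vocab)), dtype=np.float32)
    for i, g in enumerate(go_annots.gene_ids):
        for c in go_annots.assignments.get(g, ()):
            j = idx.get(c)
            if j is not None:
                go_block[i, j] = 1.0

    expr_block = None
    if expression is not None:
        k = expression.shape[1]
        expr_block = np.zeros((n, k), dtype=np.float64)
        for i, g in enumerate(go_annots.gene_ids):
            if g not in expression.index:
                continue
            row = expression.loc[g].to_numpy(dtype=np.float64)
            finite = np.isfinite(row)
            if finite.sum() >= 2 and np.nanstd(row) > 0:
                z = (row - np.nanmean(row)) / np.nanstd(row)
            else:
                z = np.zeros_like(row)
            z[~finite] = 0.0
            expr_block[i] = z
    return FeatureMatrix(
        gene_ids=list(go_annots.gene_ids),
        go_vocab=vocab,
        go_block=go_block,
        expr_block=expr_block,
    )


def split_by_gene(
    gene_ids: Sequence[str],
    test_fraction: float = 0.2,
    valid_fraction_of_train: float = 0.1,
    folds: int = 5,
    seed: int = 0,
) -> SplitSpec:
    """Gene-level cross-validation folds.

    Each fold holds out a disjoint ``test_fraction`` of genes (the test
    partitions of all folds tile the gene list), and carves
    ``valid_fraction_of_train`` of the remaining genes out as a validation
    set.  A gene, and hence all its annotations, lands in exactly one
    partition per fold.
    """
    for frac in (test_fraction, valid_fraction_of_train):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1)")
    genes = np.asarray(list(gene_ids))
    if len(genes) < folds:
        raise ValueError("fewer genes than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    if folds == 1:
        n_test = max(1, round(len(genes) * test_fraction))
        blocks = [order[:n_test], order[n_test:]]
        test_idx = blocks[0]
        rest = blocks[1]
        n_valid = max(1, round(len(rest) * valid_fraction_of_train))
        return SplitSpec(
            folds=[
                {
                    "train": genes[rest[n_valid:]].tolist(),
                    "valid": genes[rest[:n_valid]].tolist(),
                    "test": genes[test_idx].tolist(),
                }
            ],
            seed=seed,
        )
    # contiguous blocks of the permuted order are the per-fold test sets
    # (each fold tests on 1/folds of the genes; the blocks tile the list)
    blocks = np.array_split(order, folds)
    out: list[dict[str, list[str]]] = []
    for f in range(folds):
        test_idx = blocks[f]
        rest = np.concatenate([blocks[j] for j in range(folds) if j != f])
        n_valid = max(1, round(len(rest) * valid_fraction_of_train))
        valid_idx = rest[:n_valid]
        train_idx = rest[n_valid:]
        out.append(
            {
                "train": genes[train_idx].tolist(),
                "valid": genes[valid_idx].tolist(),
                "test": genes[test_idx].tolist(),
            }
        )
    return SplitSpec(folds=out, seed=seed)
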