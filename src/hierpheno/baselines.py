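"""Baseline phenotype predictors.

Two CAFA-style baselines:

* the *naive* frequency predictor — every query gene receives each
  phenotype class with score equal to the class's training frequency
  ``N_p / N_total``;
* the *HPO2GO* co-occurrence mapping — every (phenotype, GO class) pair
  co-annotated in training is scored with the Dice coefficient
  ``2·N_{p&f} / (N_p + N_f)``, and a query gene inherits, for each
  phenotype, the best score over its GO classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AnnotationSet
from .hiermodel import PredictionMatrix, true_path_fix
from .ontology import Ontology

__all__ = ["NaiveFrequencyModel", "Hpo2GoModel", "NaivePrior", "Hpo2GoMapping"]


@dataclass(frozen=True)
class NaivePrior:
    """Per-class training frequencies N_p / N_total."""

    class_scores: Mapping[str, float]
    n_total: int

    def __getitem__(self, class_id: str) -> float:
        return self.class_scores.get(class_id, 0.0)


@dataclass(frozen=True)
class Hpo2GoMapping:
    """(phenotype, GO class) -> Dice co-occurrence score in (0, 1]."""

    pair_scores: Mapping[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, f, s) for (p, f), s in sorted(self.pair_scores.items())]
        return pd.DataFrame(rows, columns=["hpo_id", "go_id", "score"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Hpo2GoMapping":
        df = pd.read_csv(path, sep="\t", dtype={"hpo_id": str, "go_id": str})
        return cls(
            pair_scores={
                (r.hpo_id, r.go_id): float(r.score) for r in df.itertuples()
            }
        )


class NaiveFrequencyModel:
    """Most-frequent-class predictor; identical score vector for every gene."""

    def __init__(self) -> None:
        self.prior_: NaivePrior | None = None
        self.class_order_: list[str] | None = None

    def fit(self, train_phenos: AnnotationSet) -> "NaiveFrequencyModel":
        if not train_phenos.gene_ids:
            raise ValueError("empty training set")
        if not train_phenos.propagated:
            raise ValueError("naive baseline expects propagated annotations")
        counts: dict[str, int] = {}
        for s in train_phenos.assignments.values():
            for c in s:
                counts[c] = counts.get(c, 0) + 1
        n = len(train_phenos.gene_ids)
        self.prior_ = NaivePrior(
            class_scores={c: k / n for c, k in counts.items()}, n_total=n
        )
        self.class_order_ = sorted(counts)
        return self

    def predict(self, gene_ids: Sequence[str]) -> PredictionMatrix:
        if self.prior_ is None:
            raise RuntimeError("fit before predict")
        row = np.array(
            [self.prior_[c] for c in self.class_order_], dtype=np.float64
        )
        scores = np.tile(row, (len(gene_ids), 1))
        # training frequencies are already ancestor-consistent: a parent is
        # annotated at least as often as any child after propagation
        return PredictionMatrix(
            gene_ids=list(gene_ids),
            class_order=list(self.class_order_),
            scores=scores,
            consistent=True,
        )


class Hpo2GoModel:
    """Phenotype prediction through GO co-occurrence mappings."""

    def __init__(self, aggregate: Literal["max", "mean"] = "max") -> None:
        if aggregate not in ("max", "mean"):
            raise ValueError("aggregate must be 'max' or 'mean'")
        self.aggregate = aggregate
        self.mapping_: Hpo2GoMapping | None = None
        self.class_order_: list[str] | None = None

    def fit(
        self, go_annots: AnnotationSet, pheno_annots: AnnotationSet
    ) -> "Hpo2GoModel":
        shared = set(go_annots.gene_ids) & set(pheno_annots.gene_ids)
        if not shared:
            raise ValueError("GO and phenotype annotation sets share no genes")
        n_f: dict[str, int] = {}
        n_p: dict[str, int] = {}
        n_pf: dict[tuple[str, str], int] = {}
        for g in shared:
            fs = go_annots.assignments.get(g, set())
            ps = pheno_annots.assignments.get(g, set())
            for f in fs:
                n_f[f] = n_f.get(f, 0) + 1
            for p in ps:
                n_p[p] = n_p.get(p, 0) + 1
            for p in ps:
                for f in fs:
                    n_pf[(p, f)] = n_pf.get((p, f), 0) + 1
        self.mapping_ = Hpo2GoMapping(
            pair_scores={
                (p, f): 2.0 * k / (n_p[p] + n_f[f]) for (p, f), k in n_pf.items()
            }
        )
        self.class_order_ = sorted(n_p)
        return self

    def predict(
        self,
        go_annots: AnnotationSet,
        gene_ids: Sequence[str],
        ont: Ontology | None = None,
    ) -> PredictionMatrix:
        """Score each (gene, phenotype) by aggregating over the gene's GO set.

        Genes with no GO annotation get an all-zero row.  When an ontology
        is given the result is true-path fixed so ancestors outscore
        descendants.
        """
        if self.mapping_ is None:
            raise RuntimeError("fit before predict")
        order = list(self.class_order_)
        p_idx = {p: i for i, p in enumerate(order)}
        # column view: go class -> (phenotype index, score) list
        by_go: dict[str, list[tuple[int, float]]] = {}
        for (p, f), s in self.mapping_.pair_scores.items():
            by_go.setdefault(f, []).append((p_idx[p], s))
        scores = np.zeros((len(gene_ids), len(order)), dtype=np.float64)
        for i, g in enumerate(gene_ids):
            fs = go_annots.assignments.get(g, set())
            if not fs:
                continue
            if self.aggregate == "max":
                for f in fs:
                    for j, s in by_go.get(f, ()):
                        if s > scores[i, j]:
                            scores[i, j] = s
            else:
                acc = np.zeros(len(order))
                for f in fs:
                    for j, s in by_go.get(f, ()):
                        acc[j] += s
                scores[i] = acc / len(fs)
        preds = PredictionMatrix(
            gene_ids=list(gene_ids), class_order=order, scores=scores
        )
        if ont is not None:
            preds = true_path_fix(preds, ont)
        return preds
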