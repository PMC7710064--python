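"""Resnik semantic similarity and phenotype-based gene–disease ranking.

Resnik similarity of two ontology classes is the information content of
their most informative common ancestor (MICA) under a corpus-marginal IC.
Two annotation sets are compared with the best-match-average (BMA)
strategy, and candidate diseases are ranked per gene by BMA similarity of
their phenotype sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import AnnotationSet
from .ontology import ICTable, Ontology

__all__ = ["RankingReport", "resnik", "bma", "rank_diseases"]


@dataclass
class RankingReport:
    """Gene–disease ranking quality over a set of true pairs."""

    hits_at_10: float
    hits_at_100: float
    mean_rank: float
    auroc: float
    per_pair: pd.DataFrame  # gene, disease, rank, n_candidates, auroc

    def summary(self) -> str:
        return (
            f"true pairs evaluated   {len(self.per_pair)}\n"
            f"Hits@10                {self.hits_at_10:.1f}%\n"
            f"Hits@100               {self.hits_at_100:.1f}%\n"
            f"mean rank              {self.mean_rank:.2f}\n"
            f"AUROC                  {self.auroc:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "hits_at_10": self.hits_at_10,
            "hits_at_100": self.hits_at_100,
            "mean_rank": self.mean_rank,
            "auroc": self.auroc,
        }


class _MicaCache:
    """Memoised ancestor sets and pairwise Resnik values."""

    def __init__(self, ont: Ontology, ic: ICTable) -> None:
        self.ont = ont
        self.ic = ic
        self._anc: dict[str, set[str]] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def ancestors(self, c: str) -> set[str]:
        if c not in self._anc:
            self._anc[c] = self.ont.ancestors(c)
        return self._anc[c]

    def resnik(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        val = self._pair.get(key)
        if val is None:
            common = self.ancestors(c1) & self.ancestors(c2)
            val = max((self.ic[c] for c in common), default=0.0)
            self._pair[key] = val
        return val


def resnik(c1: str, c2: str, ic: ICTable, ont: Ontology) -> float:
    """IC of the most informative common (reflexive) ancestor of c1, c2."""
    if ic.mode != "marginal":
        raise ValueError("Resnik similarity expects a marginal-mode ICTable")
    common = ont.ancestors(c1) & ont.ancestors(c2)
    return max((ic[c] for c in common), default=0.0)


def bma(A, B, ic: ICTable, ont: Ontology, _cache: _MicaCache | None = None) -> float:
    """Best-match-average similarity of two class sets.

    Mean of the two directed averages: each class in A matched to its best
    partner in B, and vice versa.
    """
    A, B = list(A), list(B)
    if not A or not B:
        raise ValueError("bma requires two non-empty class sets")
    cache = _cache or _MicaCache(ont, ic)
    sim = np.array([[cache.resnik(a, b) for b in B] for a in A])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def rank_diseases(
    gene_phenos: AnnotationSet,
    disease_phenos: AnnotationSet,
    truth_pairs,
    ic: ICTable,
    ont: Ontology,
    ties: str = "average",
) -> RankingReport:
    """Rank all candidate diseases for each gene by BMA-Resnik similarity.

    ``truth_pairs`` is an iterable of (gene, disease) associations; every
    disease in ``disease_phenos`` is a candidate for every gene.  Ties are
    broken mid-rank by default (``ties`` follows scipy ``rankdata``).  The
    per-pair AUROC is (n_candidates − rank) / (n_candidates − 1), averaged
    over pairs; Hits@k is the percentage of pairs ranked in the top k.
    """
    truth_pairs = list(truth_pairs)
    diseases = list(disease_phenos.gene_ids)
    disease_index = {d: j for j, d in enumerate(diseases)}
    for g, d in truth_pairs:
        if d not in disease_index:
            raise ValueError(f"truth pair references unknown disease {d!r}")
        if g not in gene_phenos.assignments or not gene_phenos.assignments[g]:
            raise ValueError(f"truth pair references unannotated gene {g!r}")
    cache = _MicaCache(ont, ic)
    n_cand = len(diseases)
    # genes appearing in truth pairs, each scored against every disease
    rows = []
    by_gene: dict[str, list[str]] = {}
    for g, d in truth_pairs:
        by_gene.setdefault(g, []).append(d)
    # genes with identical annotation sets get identical rankings; memoise
    rank_cache: dict[frozenset, np.ndarray] = {}
    for g, true_ds in by_gene.items():
        gene_set = gene_phenos.assignments[g]
        key = frozenset(gene_set)
        ranks = rank_cache.get(key)
        if ranks is None:
            scores = np.array(
                [
                    bma(gene_set, disease_phenos.assignments[d], ic, ont,
                        _cache=cache)
                    for d in diseases
                ]
            )
            ranks = rankdata(-scores, method=ties)
            rank_cache[key] = ranks
        for d in true_ds:
            r = float(ranks[disease_index[d]])
            pair_auroc = (n_cand - r) / (n_cand - 1) if n_cand > 1 else 1.0
            rows.append((g, d, r, n_cand, pair_auroc))
    per_pair = pd.DataFrame(
        rows, columns=["gene", "disease", "rank", "n_candidates", "auroc"]
    )
    ranks = per_pair["rank"].to_numpy()
    return RankingReport(
        hits_at_10=float((ranks <= 10).mean() * 100),
        hits_at_100=float((ranks <= 100).mean() * 100),
        mean_rank=float(ranks.mean()),
        auroc=float(per_pair["auroc"].mean()),
        per_pair=per_pair,
    )
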