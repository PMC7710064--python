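"""CAFA-style evaluation: Fmax, Smin, AUPR, term-centric AUROC, and a
permutation test for interaction-network overlap of false positives.

Protein-centric metrics sweep a score threshold t over {0, 0.01, ..., 1}
and call a class *predicted* for a gene when its score is strictly greater
than t.  Precision is averaged over the m(t) genes with at least one
prediction; recall over all n genes; Fmax is the best harmonic mean on the
grid.  Smin is the smallest Euclidean combination of remaining uncertainty
(information content of missed true classes) and misinformation (IC of
wrongly predicted classes), both averaged over all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import AnnotationSet
from .hiermodel import PredictionMatrix
from .ontology import ICTable

__all__ = [
    "EvalReport",
    "OverlapTestResult",
    "evaluate",
    "fmax",
    "smin",
    "aupr",
    "term_auroc",
    "read_interactions",
    "ppi_overlap_test",
]

THRESHOLDS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class EvalReport:
    """Results container for one evaluation run."""

    fmax: float
    fmax_threshold: float
    precision_at_fmax: float
    recall_at_fmax: float
    smin: float | None = None
    aupr: float | None = None
    term_auroc: float | None = None
    n_genes: int = 0
    n_classes: int = 0
    curve: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Protein-centric evaluation",
            "=" * 42,
            f"genes evaluated        {self.n_genes}",
            f"classes evaluated      {self.n_classes}",
            f"Fmax                   {self.fmax:.3f} (t = {self.fmax_threshold:.2f})",
            f"precision at Fmax      {self.precision_at_fmax:.3f}",
            f"recall at Fmax         {self.recall_at_fmax:.3f}",
        ]
        if self.smin is not None:
            lines.append(f"Smin                   {self.smin:.3f}")
        if self.aupr is not None:
            lines.append(f"AUPR                   {self.aupr:.3f}")
        if self.term_auroc is not None:
            lines.append(f"term-centric AUROC     {self.term_auroc:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "precision_at_fmax": self.precision_at_fmax,
            "recall_at_fmax": self.recall_at_fmax,
            "smin": self.smin,
            "aupr": self.aupr,
            "term_auroc": self.term_auroc,
            "n_genes": self.n_genes,
            "n_classes": self.n_classes,
        }
        return out


def _dense_truth_and_scores(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    exclude: Iterable[str] = (),
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Align truth sets and prediction scores on a common class list.

    The evaluation label space is the union of every class in the truth
    sets and every predictable class — classes the model cannot predict
    count as false negatives, predictions outside the truth universe count
    toward precision.  ``exclude`` removes ontology roots.
    """
    if list(truth.gene_ids) != list(preds.gene_ids):
        raise ValueError(
            "truth and prediction gene lists differ "
            f"({len(truth.gene_ids)} vs {len(preds.gene_ids)} genes)"
        )
    if not truth.propagated:
        raise ValueError("truth annotations must be propagated")
    excluded = set(exclude)
    classes = sorted((truth.classes() | set(preds.class_order)) - excluded)
    idx = {c: j for j, c in enumerate(classes)}
    n, C = len(truth.gene_ids), len(classes)
    T = np.zeros((n, C), dtype=bool)
    for i, g in enumerate(truth.gene_ids):
        for c in truth.assignments.get(g, ()):
            j = idx.get(c)
            if j is not None:
                T[i, j] = True
    S = np.zeros((n, C), dtype=np.float64)
    for j_src, c in enumerate(preds.class_order):
        j = idx.get(c)
        if j is not None:
            S[:, j] = preds.scores[:, j_src]
    return classes, T, S


def _threshold_curve(
    T: np.ndarray, S: np.ndarray, ic_vec: np.ndarray | None, step: float
) -> pd.DataFrame:
    ts = np.round(np.arange(0.0, 1.0 + 1e-9, step), 10)
    n = T.shape[0]
    truth_n = T.sum(axis=1)
    rows = []
    for t in ts:
        mask = S > t
        tp = (mask & T).sum(axis=1)
        pred_n = mask.sum(axis=1)
        has_pred = pred_n > 0
        m = int(has_pred.sum())
        avg_pr = float((tp[has_pred] / pred_n[has_pred]).mean()) if m else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            rc = np.where(truth_n > 0, tp / np.maximum(truth_n, 1), 0.0)
        avg_rc = float(rc.mean())
        row = {"t": float(t), "avg_pr": avg_pr, "avg_rc": avg_rc, "m": m}
        if ic_vec is not None:
            row["ru"] = float(((T & ~mask) @ ic_vec).mean())
            row["mi"] = float(((mask & ~T) @ ic_vec).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def fmax(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    threshold_step: float = 0.01,
    exclude: Iterable[str] = (),
) -> EvalReport:
    """Protein-centric Fmax over the threshold grid."""
    classes, T, S = _dense_truth_and_scores(truth, preds, exclude)
    curve = _threshold_curve(T, S, None, threshold_step)
    return _fmax_from_curve(curve, len(truth.gene_ids), len(classes))


def _fmax_from_curve(curve: pd.DataFrame, n_genes: int, n_classes: int) -> EvalReport:
    best = (0.0, 0.0, 0.0, 0.0)  # f, t, pr, rc
    for r in curve.itertuples():
        if r.m == 0:
            continue
        denom = r.avg_pr + r.avg_rc
        f = 2 * r.avg_pr * r.avg_rc / denom if denom > 0 else 0.0
        if f > best[0]:
            best = (f, r.t, r.avg_pr, r.avg_rc)
    return EvalReport(
        fmax=best[0],
        fmax_threshold=best[1],
        precision_at_fmax=best[2],
        recall_at_fmax=best[3],
        n_genes=n_genes,
        n_classes=n_classes,
        curve=curve,
    )


def smin(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    ic: ICTable,
    threshold_step: float = 0.01,
    exclude: Iterable[str] = (),
) -> float:
    """Minimum semantic distance sqrt(ru² + mi²) over the threshold grid."""
    classes, T, S = _dense_truth_and_scores(truth, preds, exclude)
    missing = [c for c in classes if c not in ic]
    if missing:
        raise ValueError(f"no information content for classes: {missing[:10]}")
    ic_vec = np.array([ic[c] for c in classes])
    curve = _threshold_curve(T, S, ic_vec, threshold_step)
    return float(np.sqrt(curve["ru"] ** 2 + curve["mi"] ** 2).min())


def aupr(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    threshold_step: float = 0.01,
    micro: bool = False,
    exclude: Iterable[str] = (),
) -> float:
    """Area under the precision–recall curve.

    Default: trapezoidal area under the averaged (AvgRc(t), AvgPr(t))
    points of the threshold grid (thresholds where no gene has a
    prediction are dropped; the curve is anchored at recall 0 with its
    lowest-recall precision).  ``micro=True`` instead flattens the
    gene × class matrices and uses average precision.
    """
    classes, T, S = _dense_truth_and_scores(truth, preds, exclude)
    if micro:
        if T.sum() == 0:
            raise ValueError("no positive (gene, class) pairs in truth")
        return float(average_precision_score(T.ravel(), S.ravel()))
    curve = _threshold_curve(T, S, None, threshold_step)
    pts = curve[curve["m"] > 0][["avg_rc", "avg_pr"]].to_numpy()
    if len(pts) == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    rc = np.concatenate([[0.0], pts[:, 0]])
    pr = np.concatenate([[pts[0, 1]], pts[:, 1]])
    return float(np.trapezoid(pr, rc))


def term_auroc(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    exclude: Iterable[str] = (),
) -> float:
    """Mean per-class AUROC over classes with ≥1 positive and ≥1 negative."""
    classes, T, S = _dense_truth_and_scores(truth, preds, exclude)
    n = T.shape[0]
    aurocs = []
    for j in range(len(classes)):
        pos = int(T[:, j].sum())
        if pos == 0 or pos == n:
            continue
        col = S[:, j]
        if np.all(col == col[0]):
            aurocs.append(0.5)  # constant scores: every ranking tie
        else:
            aurocs.append(float(roc_auc_score(T[:, j], col)))
    if not aurocs:
        raise ValueError("no class with both positive and negative genes")
    return float(np.mean(aurocs))


def evaluate(
    truth: AnnotationSet,
    preds: PredictionMatrix,
    ic: ICTable | None = None,
    threshold_step: float = 0.01,
    exclude: Iterable[str] = (),
) -> EvalReport:
    """Full protein-centric + term-centric report."""
    classes, T, S = _dense_truth_and_scores(truth, preds, exclude)
    ic_vec = None
    if ic is not None:
        missing = [c for c in classes if c not in ic]
        if missing:
            raise ValueError(f"no information content for classes: {missing[:10]}")
        ic_vec = np.array([ic[c] for c in classes])
    curve = _threshold_curve(T, S, ic_vec, threshold_step)
    report = _fmax_from_curve(curve, len(truth.gene_ids), len(classes))
    if ic_vec is not None:
        report.smin = float(np.sqrt(curve["ru"] ** 2 + curve["mi"] ** 2).min())
    report.aupr = aupr(truth, preds, threshold_step, exclude=exclude)
    try:
        report.term_auroc = term_auroc(truth, preds, exclude=exclude)
    except ValueError:
        report.term_auroc = None
    return report


# ---------------------------------------------------------------- PPI test


@dataclass(frozen=True)
class OverlapTestResult:
    """Permutation test of network adjacency between predicted and known genes."""

    observed_mean_overlap: float
    null_mean: float
    p_value: float
    n_permutations: int

    def summary(self) -> str:
        return (
            f"observed mean overlap  {self.observed_mean_overlap:.3f}\n"
            f"null mean overlap      {self.null_mean:.3f}\n"
            f"p-value                {self.p_value:.4g} "
            f"({self.n_permutations} permutations)"
        )


def read_interactions(path, cutoff: float = 0.7) -> list[tuple[str, str]]:
    """Read a 3-column (gene_a, gene_b, score) TSV of undirected edges.

    Scores on STRING's 0–999 scale are detected by their maximum and
    rescaled to 0–1 before applying the confidence ``cutoff``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    a, b, s = df.columns[:3]
    scores = df[s].to_numpy(dtype=float)
    if np.nanmax(scores) > 1.0:
        scores = scores / 999.0
    keep = scores >= cutoff
    edges = set()
    for ga, gb in df.loc[keep, [a, b]].itertuples(index=False):
        if ga != gb:
            edges.add((min(ga, gb), max(ga, gb)))
    return sorted(edges)


def ppi_overlap_test(
    pred_sets: Mapping[str, set[str]],
    known_sets: Mapping[str, set[str]],
    edges: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> OverlapTestResult:
    """Do false-positive predictions interact with known phenotype genes?

    For each phenotype, the statistic is the fraction of predicted genes
    that are *not* known (false positives) but are network-adjacent to at
    least one known gene; the reported overlap is its mean over
    phenotypes.  The null replaces each predicted set by a uniform random
    gene set of the same size; the p-value uses the add-one rule
    p = (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    if not any(known_sets.get(p) for p in pred_sets):
        raise ValueError("all known gene sets are empty")
    neighbours: dict[str, set[str]] = {}
    for ga, gb in edges:
        neighbours.setdefault(ga, set()).add(gb)
        neighbours.setdefault(gb, set()).add(ga)
    if universe is None:
        pool: set[str] = set(neighbours)
        for s in pred_sets.values():
            pool |= s
        for s in known_sets.values():
            pool |= s
        universe = sorted(pool)
    universe = np.asarray(list(universe))

    def mean_overlap(sets: Mapping[str, Iterable[str]]) -> float:
        fracs = []
        for pheno, predicted in sets.items():
            known = known_sets.get(pheno, set())
            if not known:
                continue
            fps = [g for g in predicted if g not in known]
            if not fps:
                continue
            hit = sum(1 for g in fps if neighbours.get(g, set()) & known)
            fracs.append(hit / len(fps))
        return float(np.mean(fracs)) if fracs else 0.0

    observed = mean_overlap(pred_sets)
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_perm)
    sizes = {p: len(s) for p, s in pred_sets.items()}
    for r in range(n_perm):
        random_sets = {
            p: set(rng.choice(universe, size=min(k, len(universe)), replace=False))
            for p, k in sizes.items()
        }
        null_stats[r] = mean_overlap(random_sets)
    p_value = (1 + int((null_stats >= observed).sum())) / (1 + n_perm)
    return OverlapTestResult(
        observed_mean_overlap=observed,
        null_mean=float(null_stats.mean()),
        p_value=float(p_value),
        n_permutations=n_perm,
    )
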