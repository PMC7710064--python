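"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive re-implementations (edge
relaxation for closures, exhaustive threshold enumeration for metrics,
pairwise comparisons for AUROC) kept independent of the package code they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hierpheno import Ontology


# ----------------------------------------------------------------- oracles


def oracle_ancestors(classes, edges, start):
    """Reflexive ancestor set by repeated edge relaxation (child->parent)."""
    reach = {start}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if child in reach and parent not in reach:
                reach.add(parent)
                changed = True
    return reach


def oracle_descendants(classes, edges, start):
    reach = {start}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if parent in reach and child not in reach:
                reach.add(child)
                changed = True
    return reach


def random_dag(rng, n_nodes, max_parents=3, prefix="T"):
    """(classes, edges, Ontology) for a random single-rooted DAG."""
    classes = [f"{prefix}:{i:04d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        for p in rng.choice(i, size=k, replace=False):
            edges.append((classes[i], classes[int(p)]))
    return classes, edges, Ontology.from_edges(classes, edges)


def oracle_protein_centric(truth_sets, score_rows, classes, step=0.01):
    """Exhaustive threshold enumeration of AvgPr/AvgRc/Fmax.

    ``truth_sets``: list of per-gene class sets; ``score_rows``: list of
    per-gene {class: score} dicts.  Pure-python, one loop per threshold.
    """
    n = len(truth_sets)
    points = []
    n_steps = round(1.0 / step)
    for ti in range(n_steps + 1):
        t = ti * step
        prs, rcs = [], 0.0
        m = 0
        for truth, scores in zip(truth_sets, score_rows):
            pred = {c for c in classes if scores.get(c, 0.0) > t}
            tp = len(pred & truth)
            if pred:
                m += 1
                prs.append(tp / len(pred))
            if truth:
                rcs += tp / len(truth)
        avg_pr = sum(prs) / m if m else 0.0
        avg_rc = rcs / n
        points.append((t, avg_pr, avg_rc, m))
    fmax = 0.0
    for t, p, r, m in points:
        if m and p + r > 0:
            fmax = max(fmax, 2 * p * r / (p + r))
    return points, fmax


def oracle_smin(truth_sets, score_rows, classes, ic, step=0.01):
    n = len(truth_sets)
    best = math.inf
    n_steps = round(1.0 / step)
    for ti in range(n_steps + 1):
        t = ti * step
        ru = mi = 0.0
        for truth, scores in zip(truth_sets, score_rows):
            pred = {c for c in classes if scores.get(c, 0.0) > t}
            ru += sum(ic[c] for c in truth - pred)
            mi += sum(ic[c] for c in pred - truth)
        best = min(best, math.hypot(ru / n, mi / n))
    return best


def oracle_aupr(truth_sets, score_rows, classes, step=0.01):
    """Trapezoid over the recall-sorted (AvgRc, AvgPr) grid points with an
    anchor at recall 0."""
    points, _ = oracle_protein_centric(truth_sets, score_rows, classes, step)
    pts = sorted((r, p) for t, p, r, m in points if m > 0)
    if not pts:
        return 0.0
    xs = [0.0] + [r for r, _ in pts]
    ys = [pts[0][1]] + [p for _, p in pts]
    area = 0.0
    for i in range(1, len(xs)):
        area += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2
    return area


def oracle_auroc(labels, scores):
    """Mann–Whitney pairwise AUROC with ties counted 0.5."""
    pos = [s for lab, s in zip(labels, scores) if lab]
    neg = [s for lab, s in zip(labels, scores) if not lab]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def chain_ontology():
    """A <- B <- C: C is_a B is_a A."""
    return Ontology.from_edges(["A", "B", "C"], [("B", "A"), ("C", "B")])


@pytest.fixture
def diamond_ontology():
    """D is_a B, D is_a C; B, C is_a A."""
    return Ontology.from_edges(
        ["A", "B", "C", "D"], [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")]
    )


@pytest.fixture
def chain5_ontology():
    """Five-class chain used by the worked metric fixture."""
    ids = [f"HP:{i}" for i in range(5)]
    return Ontology.from_edges(ids, [(ids[i], ids[i - 1]) for i in range(1, 5)])


@pytest.fixture(scope="session")
def planted_small():
    """A small noiseless planted dataset shared across test modules."""
    from hierpheno import simulate as sim

    return sim.gen_planted(
        go_ont=sim.gen_ontology(80, seed=21, prefix="GO"),
        hpo_ont=sim.gen_ontology(40, seed=22, prefix="HP"),
        n_genes=120,
        rule_size=2,
        noise_rate=0.0,
        expression_tissues=7,
        seed=20,
        rule_carry_prob=0.15,
    )
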