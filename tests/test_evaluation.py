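"""CAFA-style metrics against exhaustive oracles; PPI overlap test."""

import numpy as np
import pytest

from hierpheno import (
    AnnotationSet,
    PredictionMatrix,
    aupr,
    conditional_ic,
    evaluate,
    fmax,
    ppi_overlap_test,
    read_interactions,
    smin,
    term_auroc,
)
from hierpheno import simulate as sim

from conftest import (
    oracle_aupr,
    oracle_auroc,
    oracle_protein_centric,
    oracle_smin,
)


@pytest.fixture
def worked_fixture(chain5_ontology):
    """Two genes over the 5-class chain with hand-specified scores."""
    ids = [f"HP:{i}" for i in range(5)]
    truth = AnnotationSet(
        gene_ids=["g1", "g2"],
        assignments={
            "g1": {ids[0], ids[1], ids[2]},
            "g2": {ids[0], ids[1], ids[2], ids[3], ids[4]},
        },
        propagated=True,
    )
    scores = np.array(
        [
            [0.90, 0.70, 0.30, 0.30, 0.05],
            [0.80, 0.80, 0.60, 0.20, 0.10],
        ]
    )
    preds = PredictionMatrix(gene_ids=["g1", "g2"], class_order=ids, scores=scores)
    return chain5_ontology, ids, truth, preds, scores


class TestFmax:
    def test_perfect_predictor(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        perfect = PredictionMatrix(
            gene_ids=truth.gene_ids,
            class_order=ids,
            scores=np.array([[1.0, 1.0, 1.0, 0.0, 0.0],
                             [1.0, 1.0, 1.0, 1.0, 1.0]]),
        )
        assert fmax(truth, perfect).fmax == pytest.approx(1.0)

    def test_all_zero_scores_give_zero(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        zero = PredictionMatrix(
            gene_ids=truth.gene_ids, class_order=ids,
            scores=np.zeros((2, 5)),
        )
        assert fmax(truth, zero).fmax == 0.0

    def test_worked_fixture_matches_threshold_oracle(self, worked_fixture):
        ont, ids, truth, preds, scores = worked_fixture
        report = fmax(truth, preds)
        truth_sets = [truth.assignments[g] for g in truth.gene_ids]
        score_rows = [dict(zip(ids, row)) for row in scores]
        points, expected_fmax = oracle_protein_centric(truth_sets, score_rows, ids)
        assert report.fmax == pytest.approx(expected_fmax, abs=1e-12)
        # the whole curve agrees, threshold by threshold
        for (t, p, r, m), row in zip(points, report.curve.itertuples()):
            assert row.t == pytest.approx(t)
            assert row.avg_pr == pytest.approx(p, abs=1e-12)
            assert row.avg_rc == pytest.approx(r, abs=1e-12)
            assert row.m == m

    def test_gene_list_mismatch_rejected(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        other = PredictionMatrix(gene_ids=["gX"], class_order=ids,
                                 scores=np.zeros((1, 5)))
        with pytest.raises(ValueError, match="gene lists differ"):
            fmax(truth, other)

    def test_invariant_under_grid_preserving_rescale(self, worked_fixture):
        ont, ids, truth, preds, scores = worked_fixture
        # squaring is strictly monotone on [0,1]; recompute on the same grid
        squared = PredictionMatrix(gene_ids=truth.gene_ids, class_order=ids,
                                   scores=scores**2)
        # Fmax (the max over the grid) is preserved because the predicted
        # sets at threshold t^2 equal the original sets at t
        assert fmax(truth, squared).fmax == pytest.approx(
            fmax(truth, preds).fmax, abs=1e-9)


class TestSmin:
    def test_perfect_predictions_give_zero(self, worked_fixture, chain5_ontology):
        ont, ids, truth, preds, _ = worked_fixture
        ic = conditional_ic(truth, chain5_ontology)
        perfect = PredictionMatrix(
            gene_ids=truth.gene_ids, class_order=ids,
            scores=np.array([[1.0, 1.0, 1.0, 0.0, 0.0],
                             [1.0, 1.0, 1.0, 1.0, 1.0]]),
        )
        assert smin(truth, perfect, ic) == pytest.approx(0.0)

    def test_empty_predictions_give_mean_total_ic(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        ic = conditional_ic(truth, ont)
        zero = PredictionMatrix(gene_ids=truth.gene_ids, class_order=ids,
                                scores=np.zeros((2, 5)))
        expected = np.mean([
            sum(ic[c] for c in truth.assignments[g]) for g in truth.gene_ids
        ])
        assert smin(truth, zero, ic) == pytest.approx(expected)

    def test_worked_fixture_matches_oracle(self, worked_fixture):
        ont, ids, truth, preds, scores = worked_fixture
        ic = conditional_ic(truth, ont)
        truth_sets = [truth.assignments[g] for g in truth.gene_ids]
        score_rows = [dict(zip(ids, row)) for row in scores]
        ic_map = {c: ic[c] for c in ids}
        assert smin(truth, preds, ic) == pytest.approx(
            oracle_smin(truth_sets, score_rows, ids, ic_map), abs=1e-12)

    def test_missing_ic_class_reported(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        from hierpheno import ICTable
        partial = ICTable(mode="conditional",
                          values={ids[0]: 0.0}, corpus_size=2)
        with pytest.raises(ValueError, match="HP:1"):
            smin(truth, preds, partial)


class TestAupr:
    def test_perfect_predictor_is_one(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        perfect = PredictionMatrix(
            gene_ids=truth.gene_ids, class_order=ids,
            scores=np.array([[1.0, 1.0, 1.0, 0.0, 0.0],
                             [1.0, 1.0, 1.0, 1.0, 1.0]]),
        )
        assert aupr(truth, perfect) == pytest.approx(1.0)

    def test_all_zero_scores_give_zero(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        zero = PredictionMatrix(gene_ids=truth.gene_ids, class_order=ids,
                                scores=np.zeros((2, 5)))
        assert aupr(truth, zero) == 0.0

    def test_worked_fixture_matches_trapezoid_oracle(self, worked_fixture):
        ont, ids, truth, preds, scores = worked_fixture
        truth_sets = [truth.assignments[g] for g in truth.gene_ids]
        score_rows = [dict(zip(ids, row)) for row in scores]
        assert aupr(truth, preds) == pytest.approx(
            oracle_aupr(truth_sets, score_rows, ids), abs=1e-12)


class TestTermAuroc:
    def test_constant_scores_are_half(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        const = PredictionMatrix(gene_ids=truth.gene_ids, class_order=ids,
                                 scores=np.full((2, 5), 0.4))
        assert term_auroc(truth, const) == pytest.approx(0.5)

    def test_perfect_separation_is_one(self):
        truth = AnnotationSet(
            gene_ids=["a", "b", "c", "d"],
            assignments={"a": {"HP:x"}, "b": {"HP:x"}, "c": set(), "d": set()},
            propagated=True,
        )
        preds = PredictionMatrix(
            gene_ids=["a", "b", "c", "d"], class_order=["HP:x"],
            scores=np.array([[0.9], [0.8], [0.2], [0.1]]),
        )
        assert term_auroc(truth, preds) == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(61)
        genes = [f"g{i}" for i in range(20)]
        classes = [f"HP:{j}" for j in range(6)]
        T = rng.random((20, 6)) < 0.4
        T[:, 0] = True  # root-like, not evaluable
        scores = np.round(rng.random((20, 6)), 1)  # coarse -> plenty of ties
        truth = AnnotationSet(
            gene_ids=genes,
            assignments={g: {c for j, c in enumerate(classes) if T[i, j]}
                         for i, g in enumerate(genes)},
            propagated=True,
        )
        preds = PredictionMatrix(gene_ids=genes, class_order=classes,
                                 scores=scores)
        expected = []
        for j in range(6):
            pos = T[:, j].sum()
            if pos == 0 or pos == 20:
                continue
            expected.append(oracle_auroc(T[:, j], scores[:, j]))
        assert term_auroc(truth, preds) == pytest.approx(np.mean(expected))

    def test_invariant_under_monotone_rescale(self):
        rng = np.random.default_rng(67)
        genes = [f"g{i}" for i in range(30)]
        T = rng.random((30, 4)) < 0.5
        classes = [f"HP:{j}" for j in range(4)]
        truth = AnnotationSet(
            gene_ids=genes,
            assignments={g: {c for j, c in enumerate(classes) if T[i, j]}
                         for i, g in enumerate(genes)},
            propagated=True,
        )
        scores = rng.random((30, 4))
        a = term_auroc(truth, PredictionMatrix(gene_ids=genes,
                                               class_order=classes,
                                               scores=scores))
        b = term_auroc(truth, PredictionMatrix(gene_ids=genes,
                                               class_order=classes,
                                               scores=np.sqrt(scores)))
        assert a == pytest.approx(b)


class TestEvaluateWrapper:
    def test_report_fields_and_truth_repropagation(self, worked_fixture):
        ont, ids, truth, preds, _ = worked_fixture
        from hierpheno import propagate
        ic = conditional_ic(truth, ont)
        r1 = evaluate(truth, preds, ic=ic)
        r2 = evaluate(propagate(ont, truth), preds, ic=ic)
        assert r1.fmax == pytest.approx(r2.fmax)
        assert r1.smin == pytest.approx(r2.smin)
        assert r1.aupr == pytest.approx(r2.aupr)
        assert "Fmax" in r1.summary()


class TestOverlapTest:
    def _sets(self):
        known = {"HP:p": {"g00000", "g00001", "g00002", "g00003"}}
        pred = {"HP:p": {"g00004", "g00005", "g00006"}}
        return pred, known

    def test_planted_clique_significant(self):
        pred, known = self._sets()
        # predictions drawn from the clique's neighborhood: make known genes
        # a clique and connect each predicted gene to a known gene
        edges = sim.gen_interaction_graph(known, n_genes=60,
                                          clique_density=1.0,
                                          background_density=0.0, seed=5)
        extra = [(g, "g00000") for g in pred["HP:p"]]
        result = ppi_overlap_test(pred, known, edges + extra,
                                  n_perm=1000, seed=9,
                                  universe=[f"g{i:05d}" for i in range(60)])
        assert result.observed_mean_overlap == pytest.approx(1.0)
        assert result.p_value <= 0.05
        assert result.null_mean < result.observed_mean_overlap

    def test_edgeless_graph(self):
        pred, known = self._sets()
        result = ppi_overlap_test(pred, known, [], n_perm=200, seed=1,
                                  universe=[f"g{i:05d}" for i in range(60)])
        assert result.observed_mean_overlap == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_add_one_p_value_rule(self):
        pred, known = self._sets()
        edges = [(g, "g00000") for g in pred["HP:p"]]
        result = ppi_overlap_test(pred, known, edges, n_perm=100, seed=3)
        assert 0.0 < result.p_value <= 1.0
        assert result.p_value >= 1.0 / 101.0

    def test_all_known_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ppi_overlap_test({"HP:p": {"a"}}, {"HP:p": set()}, [])


class TestReadInteractions:
    def test_string_scale_autodetected(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("gene_a\tgene_b\tscore\na\tb\t900\nb\tc\t400\n")
        edges = read_interactions(p, cutoff=0.7)
        assert edges == [("a", "b")]

    def test_unit_scale_and_dedup(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("gene_a\tgene_b\tscore\na\tb\t0.9\nb\ta\t0.8\na\ta\t0.99\n")
        assert read_interactions(p) == [("a", "b")]
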