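"""Artificial-doublet construction and pair-SVM classification of PICs."""

import numpy as np
import pytest

import picseq as pq
from picseq.data_model import CountMatrix, PairLabel, PicseqError
from picseq.pic_classifier import (
    build_training_set,
    classify_pics,
    cross_validate,
    heterotypic_enrichment,
    make_artificial_doublet,
    train_pair_svm,
)
from picseq.stats import ContingencyTable2x2, fisher_exact


class TestArtificialDoublet:
    def test_elementwise_sum(self):
        assert make_artificial_doublet(
            np.array([1, 0, 2]), np.array([0, 3, 1])
        ).tolist() == [1, 3, 3]

    def test_zero_vector_is_identity_and_totals_conserved(self):
        a = np.array([4, 1, 0])
        assert make_artificial_doublet(a, np.zeros(3, int)).tolist() == a.tolist()
        b = np.array([2, 2, 2])
        assert make_artificial_doublet(a, b).sum() == a.sum() + b.sum()

    def test_mismatched_universes_rejected(self):
        with pytest.raises(PicseqError):
            make_artificial_doublet(np.array([1, 2]), np.array([1, 2, 3]))


def _tiny_singles():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 9, size=(6, 8))
    samples = [f"s{i}" for i in range(8)]
    labels = dict(zip(samples, ["A", "A", "A", "B", "B", "B", "C", "C"]))
    return CountMatrix([f"g{i}" for i in range(6)], samples, counts), labels


class TestBuildTrainingSet:
    def test_three_clusters_give_six_classes(self):
        singles, labels = _tiny_singles()
        ts = build_training_set(singles, labels, ["A", "B", "C"], n_per_class=4, seed=1)
        assert ts.matrix.n_samples == 6 * 4
        assert len(set(ts.labels)) == 6

    def test_seeded_determinism_of_provenance(self):
        singles, labels = _tiny_singles()
        t1 = build_training_set(singles, labels, ["A", "B"], n_per_class=5, seed=9)
        t2 = build_training_set(singles, labels, ["A", "B"], n_per_class=5, seed=9)
        assert t1.provenance == t2.provenance
        assert np.array_equal(t1.matrix.counts, t2.matrix.counts)

    def test_doublets_are_sums_and_homotypic_members_distinct(self):
        singles, labels = _tiny_singles()
        ts = build_training_set(singles, labels, ["A", "B"], n_per_class=6, seed=2)
        col = {s: i for i, s in enumerate(singles.sample_ids)}
        for j, (a, b) in enumerate(ts.provenance):
            assert np.array_equal(
                ts.matrix.counts[:, j], singles.counts[:, col[a]] + singles.counts[:, col[b]]
            )
            if ts.labels[j].is_homotypic:
                assert a != b

    def test_small_cluster_rejected(self):
        singles, labels = _tiny_singles()
        labels = dict(labels, s7="D")  # D has one cell
        with pytest.raises(PicseqError, match="D"):
            build_training_set(singles, labels, ["A", "D"], n_per_class=2, seed=0)


class TestTrainAndClassify:
    def _separable_training(self):
        # class A+A high in g0, B+B high in g1: trivially separable
        rng = np.random.default_rng(1)
        base = rng.integers(5, 10, size=(3, 40))
        base[0, :20] += 200
        base[1, 20:] += 200
        m = CountMatrix(["g0", "g1", "g2"], [f"d{i}" for i in range(40)], base)
        labels = [PairLabel("A", "A")] * 20 + [PairLabel("B", "B")] * 20
        prov = [("x", "y")] * 40
        return pq.ArtificialDoubletSet(m, labels, prov, seed=0)

    def test_separable_classes_reach_perfect_training_accuracy(self):
        ts = self._separable_training()
        clf = train_pair_svm(ts, ["g0", "g1", "g2"])
        assert classify_pics(clf, ts.matrix) == ts.labels

    def test_conflicting_duplicates_do_not_crash(self):
        m = CountMatrix(
            ["g0"], [f"d{i}" for i in range(8)], np.full((1, 8), 7)
        )
        labels = [PairLabel("A", "A")] * 4 + [PairLabel("B", "B")] * 4
        ts = pq.ArtificialDoubletSet(m, labels, [("x", "y")] * 8, seed=0)
        clf = train_pair_svm(ts, ["g0"])
        pred = classify_pics(clf, m)
        assert sum(p == l for p, l in zip(pred, labels)) < 8

    def test_missing_feature_gene_is_named(self):
        ts = self._separable_training()
        with pytest.raises(PicseqError, match="g9"):
            train_pair_svm(ts, ["g0", "g9"])

    def test_empty_pic_set_gives_empty_output(self, pair_classifier, sim):
        empty = CountMatrix(list(sim.singles.gene_ids), [], np.zeros((sim.singles.n_genes, 0), int))
        assert classify_pics(pair_classifier, empty) == []

    def test_classification_is_deterministic(self, pair_classifier, sim):
        p1 = classify_pics(pair_classifier, sim.pics)
        p2 = classify_pics(pair_classifier, sim.pics)
        assert p1 == p2


class TestCrossValidation:
    def test_class_smaller_than_k_rejected(self):
        singles, labels = _tiny_singles()
        ts = build_training_set(singles, labels, ["A", "B"], n_per_class=5, seed=3)
        with pytest.raises(PicseqError):
            cross_validate(ts, list(singles.gene_ids), k=10, seed=0)

    def test_leave_one_out_runs(self):
        singles, labels = _tiny_singles()
        ts = build_training_set(singles, labels, ["A", "B"], n_per_class=10, seed=3)
        err = cross_validate(ts, list(singles.gene_ids), k=10, seed=0)
        assert 0.0 <= err <= 1.0

    def test_shuffled_labels_give_chance_error(self, sim):
        """Uniformly shuffled pair labels: error ~ 1 - 1/C for C classes."""
        ts = pq.build_training_set(
            sim.singles, sim.labels, list(sim.cfg.type_names), n_per_class=30, seed=5
        )
        rng = np.random.default_rng(6)
        shuffled = [ts.labels[i] for i in rng.permutation(len(ts.labels))]
        null = pq.ArtificialDoubletSet(ts.matrix, shuffled, ts.provenance, seed=5)
        feats = [g for g in sim.singles.gene_ids[:40]]
        err = cross_validate(null, feats, k=10, seed=7)
        n_classes = len(set(map(str, ts.labels)))
        assert abs(err - (1 - 1 / n_classes)) < 0.1


class TestDefaultSimulationPerformance:
    def test_pic_pair_labels_recovered(self, pair_classifier, sim):
        pred = classify_pics(pair_classifier, sim.pics)
        acc = np.mean([p == sim.truth.pic_labels[s] for s, p in zip(sim.pics.sample_ids, pred)])
        assert acc > 0.78

    def test_homotypic_pics_mostly_labeled_homotypic(self, pair_classifier, sim):
        pred = classify_pics(pair_classifier, sim.pics)
        pairs = [
            (sim.truth.pic_labels[s], p)
            for s, p in zip(sim.pics.sample_ids, pred)
            if sim.truth.pic_labels[s].is_homotypic
        ]
        assert np.mean([t == p for t, p in pairs]) > 0.75

    def test_literal_np_de_sum_is_labeled_np_de(self, pair_classifier, sim):
        rng = np.random.default_rng(8)
        np_cells = [s for s in sim.singles.sample_ids if sim.labels[s] == "NP"]
        de_cells = [s for s in sim.singles.sample_ids if sim.labels[s] == "DE"]
        cols, ids = [], []
        for i in range(40):
            a, b = rng.choice(np_cells), rng.choice(de_cells)
            cols.append(sim.singles.column(a) + sim.singles.column(b))
            ids.append(f"lit{i}")
        lit = CountMatrix(list(sim.singles.gene_ids), ids, np.stack(cols, axis=1))
        pred = classify_pics(pair_classifier, lit)
        assert np.mean([p == PairLabel("NP", "DE") for p in pred]) >= 0.7


def test_relabeling_types_permutes_outputs(sim, feature_genes):
    """Order-preserving renaming of cell types maps predictions consistently."""
    mapping = {"DE": "T1de", "FG": "T2fg", "NC": "T3nc", "NP": "T4np"}
    labels2 = {s: mapping[t] for s, t in sim.labels.items()}
    ts1 = pq.build_training_set(sim.singles, sim.labels, sorted(sim.cfg.type_names),
                                n_per_class=50, seed=13)
    ts2 = pq.build_training_set(sim.singles, labels2, sorted(mapping.values()),
                                n_per_class=50, seed=13)
    clf1 = train_pair_svm(ts1, feature_genes)
    clf2 = train_pair_svm(ts2, feature_genes)
    p1 = classify_pics(clf1, sim.pics)
    p2 = classify_pics(clf2, sim.pics)
    mapped = [PairLabel(mapping[p.type_a], mapping[p.type_b]) for p in p1]
    assert mapped == p2


class TestHeterotypicEnrichment:
    def test_proportional_tables_are_null(self):
        pics = {PairLabel("A", "B"): 10, PairLabel("A", "A"): 30}
        dbl = {PairLabel("A", "B"): 5, PairLabel("A", "A"): 15}
        res = heterotypic_enrichment(pics, dbl)
        assert all(r.test.p_value >= 0.99 for r in res.values())

    def test_enriched_pair_matches_fisher_oracle(self):
        pair = PairLabel("A", "B")
        pics = {pair: 20, PairLabel("A", "A"): 20}
        dbl = {pair: 1, PairLabel("A", "A"): 39}
        res = heterotypic_enrichment(pics, dbl)
        direct = fisher_exact(ContingencyTable2x2(20, 20, 1, 39))
        assert res[pair].test.p_value == pytest.approx(direct.p_value)

    def test_missing_entries_count_as_zero(self):
        pics = {PairLabel("A", "B"): 4, PairLabel("A", "A"): 6}
        dbl = {PairLabel("A", "A"): 10}
        res = heterotypic_enrichment(pics, dbl)
        assert res[PairLabel("A", "B")].doublet_count == 0
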