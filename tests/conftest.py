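"""Shared fixtures: one default synthetic embryo and the models built on it.

Session-scoped so the simulation, marker scan and SVM training run once for
the whole suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import picseq as pq
from picseq.data_model import PairLabel


@dataclass
class SimBundle:
    cfg: object
    singles: object
    single_annotations: list
    pics: object
    pic_annotations: list
    truth: object

    @property
    def labels(self) -> dict:
        return {a.sample_id: a.label for a in self.single_annotations}


@pytest.fixture(scope="session")
def sim() -> SimBundle:
    cfg = pq.default_config()
    return SimBundle(cfg, *pq.simulate_embryo(cfg))


@pytest.fixture(scope="session")
def norm(sim):
    return pq.normalize(sim.singles)


@pytest.fixture(scope="session")
def marker_results(sim, norm):
    return pq.find_markers(norm, sim.labels)


@pytest.fixture(scope="session")
def feature_genes(marker_results):
    return pq.feature_union(pq.top_markers(marker_results, k=5))


@pytest.fixture(scope="session")
def doublet_training(sim):
    return pq.build_training_set(
        sim.singles, sim.labels, list(sim.cfg.type_names), n_per_class=200, seed=11
    )


@pytest.fixture(scope="session")
def pair_classifier(doublet_training, feature_genes):
    return pq.train_pair_svm(doublet_training, feature_genes, stage="E8.5")


@pytest.fixture(scope="session")
def contact_results(sim):
    """Contact-gene scans for both planted pairs, using ground-truth PIC labels."""
    out = {}
    for pair in (PairLabel("NP", "DE"), PairLabel("NP", "NC")):
        out[pair] = pq.detect_contact_genes(
            sim.pics, sim.truth.pic_labels, sim.singles, sim.labels, pair, seed=5
        )
    return out


@pytest.fixture(scope="session")
def neighbor_classifier(sim, contact_results):
    feats = pq.contact_gene_union(contact_results, "NP")
    pairs = [PairLabel("NP", "NP"), PairLabel("NP", "DE"), PairLabel("NP", "NC")]
    return pq.train_neighbor_svm("NP", sim.pics, sim.truth.pic_labels, feats, pairs=pairs)
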