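"""Pair classification of PIC transcriptomes via SVMs on artificial doublets.

A PIC (physically interacting cells) library is approximately the sum of two
single cells' molecule counts.  Labeled training data is therefore
manufactured in silico: artificial doublets, each the elementwise sum of two
randomly chosen single cells, labeled by the unordered pair of their source
cell types (homotypic pairs included).  A multiclass SVM — one linear binary
learner per class pair, one-vs-one, majority vote with ties broken by summed
decision margins — is trained on these doublets using the union of the top
marker genes per cluster as features, then applied to the observed PICs.

Enrichment of a pair among PICs relative to sequencing doublets (whose pair
counts are an input, e.g. from a doublet-detection tool) is scored by
Fisher's exact test with BH correction across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsOneClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_SCALE_FACTOR,
    CountMatrix,
    PairLabel,
    PicseqError,
    normalize,
)
from .stats import ContingencyTable2x2, TestResult, bh_fdr, fisher_exact

N_PER_CLASS_DEFAULT = 200
SVM_C_DEFAULT = 1.0


def make_artificial_doublet(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise sum of two count vectors over the same gene universe."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise PicseqError(
            f"mismatched gene universes: {a.shape} vs {b.shape}"
        )
    return a + b


@dataclass
class ArtificialDoubletSet:
    """Synthetic doublets with pair labels and source-cell provenance."""

    matrix: CountMatrix
    labels: list[PairLabel]
    provenance: list[tuple[str, str]]
    seed: int

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.provenance) == self.matrix.n_samples):
            raise PicseqError("doublet labels/provenance inconsistent with matrix")


def _label_lookup(m: CountMatrix, labels) -> dict[str, str]:
    if isinstance(labels, Mapping):
        return dict(labels)
    labels = list(labels)
    if len(labels) != m.n_samples:
        raise PicseqError(f"{len(labels)} labels for {m.n_samples} samples")
    return dict(zip(m.sample_ids, labels))


def build_training_set(
    singles: CountMatrix,
    labels,
    stage_clusters: Sequence[str],
    n_per_class: int = N_PER_CLASS_DEFAULT,
    seed: int = 0,
) -> ArtificialDoubletSet:
    """Artificial doublets for every unordered pair over ``stage_clusters``.

    ``n_per_class`` doublets per class; member cells are drawn uniformly,
    the two members of a homotypic doublet always distinct.
    """
    lookup = _label_lookup(singles, labels)
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[int]] = {c: [] for c in stage_clusters}
    for i, s in enumerate(singles.sample_ids):
        t = lookup.get(s)
        if t in by_type:
            by_type[t].append(i)
    for c in stage_clusters:
        if len(by_type[c]) < 2:
            raise PicseqError(f"cluster {c!r} has fewer than 2 cells")

    cols: list[np.ndarray] = []
    out_labels: list[PairLabel] = []
    provenance: list[tuple[str, str]] = []
    ids: list[str] = []
    for ta, tb in combinations_with_replacement(sorted(stage_clusters), 2):
        pair = PairLabel(ta, tb)
        for k in range(n_per_class):
            if ta == tb:
                ia, ib = rng.choice(by_type[ta], size=2, replace=False)
            else:
                ia = rng.choice(by_type[ta])
                ib = rng.choice(by_type[tb])
            cols.append(make_artificial_doublet(singles.counts[:, ia], singles.counts[:, ib]))
            out_labels.append(pair)
            provenance.append((singles.sample_ids[ia], singles.sample_ids[ib]))
            ids.append(f"ad_{pair}_{k:04d}")
    matrix = CountMatrix(list(singles.gene_ids), ids, np.stack(cols, axis=1))
    return ArtificialDoubletSet(matrix, out_labels, provenance, seed)


@dataclass
class PairClassifier:
    """A trained one-vs-one SVM ensemble over cell-type pair classes.

    Prediction-time normalization (depth scaling, log transform) and feature
    standardization reuse the statistics stored at training.
    """

    stage: str
    classes: list[PairLabel]
    feature_genes: list[str]
    model: OneVsOneClassifier
    scaler: StandardScaler
    scale_factor: float = DEFAULT_SCALE_FACTOR
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    svm_c: float = SVM_C_DEFAULT
    kernel: str = "linear"
    seed: int = 0

    def _features(self, m: CountMatrix) -> np.ndarray:
        """Normalized, feature-restricted, training-standardized (samples x features)."""
        norm = normalize(m, self.scale_factor, True, self.pseudocount)
        sub = norm.subset_genes(self.feature_genes)
        return self.scaler.transform(sub.values.T)

    def predict(self, m: CountMatrix) -> list[PairLabel]:
        if m.n_samples == 0:
            return []
        pred = self.model.predict(self._features(m))
        return [PairLabel.parse(p) for p in pred]


def _fit_ovo(
    X: np.ndarray, y: list[str], c: float, kernel: str, seed: int
) -> OneVsOneClassifier:
    base = SVC(kernel=kernel, C=c, random_state=seed)
    clf = OneVsOneClassifier(base)
    clf.fit(X, np.asarray(y, dtype=object))
    return clf


def train_pair_svm(
    training: ArtificialDoubletSet,
    feature_genes: Sequence[str],
    stage: str = "",
    svm_c: float = SVM_C_DEFAULT,
    kernel: str = "linear",
) -> PairClassifier:
    """Fit the pair classifier on an artificial-doublet training set.

    Doublets are depth-normalized and log-transformed, restricted to
    ``feature_genes``, and standardized per feature on the training set.
    """
    if not feature_genes:
        raise PicseqError("feature_genes must be non-empty")
    classes = sorted(set(training.labels))
    if len(classes) < 2:
        raise PicseqError("need at least 2 pair classes")
    norm = normalize(training.matrix)
    sub = norm.subset_genes(list(feature_genes))
    scaler = StandardScaler()
    X = scaler.fit_transform(sub.values.T)
    y = [str(l) for l in training.labels]
    model = _fit_ovo(X, y, svm_c, kernel, training.seed)
    return PairClassifier(
        stage=stage,
        classes=classes,
        feature_genes=list(feature_genes),
        model=model,
        scaler=scaler,
        scale_factor=norm.scale_factor,
        pseudocount=norm.pseudocount,
        svm_c=svm_c,
        kernel=kernel,
        seed=training.seed,
    )


def cross_validate(
    training: ArtificialDoubletSet,
    feature_genes: Sequence[str],
    k: int = 10,
    seed: int = 0,
    svm_c: float = SVM_C_DEFAULT,
    kernel: str = "linear",
) -> float:
    """Stratified k-fold cross-validated error rate of the pair SVM."""
    y = np.asarray([str(l) for l in training.labels], dtype=object)
    counts = {c: int((y == c).sum()) for c in set(y)}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise PicseqError(f"classes smaller than k={k}: {small}")
    norm = normalize(training.matrix)
    sub = norm.subset_genes(list(feature_genes))
    X_all = sub.values.T
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = 0
    for train_idx, test_idx in skf.split(X_all, y):
        scaler = StandardScaler()
        X_tr = scaler.fit_transform(X_all[train_idx])
        X_te = scaler.transform(X_all[test_idx])
        model = _fit_ovo(X_tr, list(y[train_idx]), svm_c, kernel, seed)
        errors += int((model.predict(X_te) != y[test_idx]).sum())
    return errors / len(y)


def classify_pics(clf: PairClassifier, pics: CountMatrix) -> list[PairLabel]:
    """Assign a pair label to each PIC; deterministic given the classifier."""
    return clf.predict(pics)


@dataclass
class PairEnrichment:
    pair: PairLabel
    pic_count: int
    doublet_count: int
    test: TestResult
    q_value: float = field(default=1.0)


def heterotypic_enrichment(
    pic_pair_counts: Mapping[PairLabel, int],
    doublet_pair_counts: Mapping[PairLabel, int],
) -> dict[PairLabel, PairEnrichment]:
    """Fisher's exact enrichment of each pair among PICs vs doublets.

    Missing entries in either map count as zero; BH correction is applied
    across the pair universe.
    """
    universe = sorted(set(pic_pair_counts) | set(doublet_pair_counts))
    if not universe:
        raise PicseqError("no pairs to test")
    total_pic = sum(pic_pair_counts.values())
    total_dbl = sum(doublet_pair_counts.values())
    results: dict[PairLabel, PairEnrichment] = {}
    for pair in universe:
        a = int(pic_pair_counts.get(pair, 0))
        c = int(doublet_pair_counts.get(pair, 0))
        table = ContingencyTable2x2(a, total_pic - a, c, total_dbl - c)
        results[pair] = PairEnrichment(pair, a, c, fisher_exact(table))
    q = bh_fdr([results[p].test.p_value for p in universe])
    for pair, qv in zip(universe, q):
        results[pair].q_value = float(qv)
    return results
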