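"""Neighbor cell-type prediction from single-cell transcriptomes.

Heterotypic contact leaves a trace in each partner's own transcriptome, so a
single cell's in-tissue neighbor type can be predicted: an SVM is trained per
focal type on the *real* PICs whose pair contains that type, using only
contact-specific genes as features.  Each single cell is then mixed in silico
with other cells one by one (count sums, like artificial doublets), every mix
is classified, and the most frequent pair class wins the vote; ties break
toward the homotypic pair (most neighbors are same-type), then
lexicographically.  The predicted partner is the non-focal member of the
winning pair.

Downstream, neighbor-specific genes per focal type are found by comparing
focal cells predicted to neighbor one partner type against the remaining
focal cells (rank-sum + BH per partner).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import CountMatrix, NormalizedMatrix, PairLabel, PicseqError
from .pic_classifier import PairClassifier, train_pair_svm, ArtificialDoubletSet
from .stats import bh_fdr, rank_sum_scan

MAX_MIXES_DEFAULT = 500
MIN_PICS_PER_CLASS = 3


@dataclass
class NeighborAssignment:
    sample_id: str
    focal_type: str
    predicted_partner: str
    votes: dict[PairLabel, int]
    n_mixes: int

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.n_mixes:
            raise PicseqError("votes must sum to n_mixes")


def train_neighbor_svm(
    focal_type: str,
    pics: CountMatrix,
    pic_labels,
    contact_gene_features: Sequence[str],
    stage: str = "",
    pairs: Sequence[PairLabel] | None = None,
) -> PairClassifier:
    """SVM over the pair classes containing ``focal_type``, fit on real PICs.

    Features are contact-specific genes only, so the class set should be the
    homotypic pair plus the heterotypic pairs those genes came from (e.g. for
    NP: NP+NP, NP+DE, NP+NC); pass it as ``pairs``.  With ``pairs=None``
    every pair containing the focal type is eligible.  Classes with fewer
    than 3 PICs are dropped; at least two eligible classes are required.
    """
    lookup = pic_labels if isinstance(pic_labels, Mapping) else dict(
        zip(pics.sample_ids, pic_labels)
    )
    wanted = None if pairs is None else set(pairs)
    by_class: dict[PairLabel, list[str]] = {}
    for s in pics.sample_ids:
        lbl = lookup.get(s)
        if not isinstance(lbl, PairLabel) or not lbl.contains(focal_type):
            continue
        if wanted is not None and lbl not in wanted:
            continue
        by_class.setdefault(lbl, []).append(s)
    by_class = {c: ids for c, ids in by_class.items() if len(ids) >= MIN_PICS_PER_CLASS}
    if len(by_class) < 2:
        raise PicseqError(
            f"focal type {focal_type!r}: need >= 2 pair classes with >= "
            f"{MIN_PICS_PER_CLASS} PICs each, have {len(by_class)}"
        )
    if not contact_gene_features:
        raise PicseqError("contact_gene_features must be non-empty")
    keep: list[str] = []
    labels: list[PairLabel] = []
    for c in sorted(by_class):
        keep.extend(by_class[c])
        labels.extend([c] * len(by_class[c]))
    training = ArtificialDoubletSet(
        matrix=pics.subset_samples(keep),
        labels=labels,
        provenance=[(s, s) for s in keep],  # real PICs: provenance is the PIC itself
        seed=0,
    )
    return train_pair_svm(training, contact_gene_features, stage=stage)


def predict_neighbor(
    cell: np.ndarray,
    focal_type: str,
    partner_pool: CountMatrix,
    clf: PairClassifier,
    max_mixes: int = MAX_MIXES_DEFAULT,
    seed: int = 0,
    sample_id: str = "cell",
) -> NeighborAssignment:
    """Vote over artificial mixes of one cell with pool cells.

    ``max_mixes=None`` mixes with the whole pool (the literal procedure);
    otherwise a uniform seeded subsample of the pool is used.
    """
    if partner_pool.n_samples == 0:
        raise PicseqError("partner pool is empty")
    cell = np.asarray(cell)
    if cell.shape != (partner_pool.n_genes,):
        raise PicseqError("cell vector does not match the pool's gene universe")
    n_pool = partner_pool.n_samples
    if max_mixes is not None and max_mixes < n_pool:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_pool, size=max_mixes, replace=False)
    else:
        idx = np.arange(n_pool)
    mixes = cell[:, None] + partner_pool.counts[:, idx]
    mix_ids = [f"mix_{sample_id}_{i}" for i in range(len(idx))]
    mix_matrix = CountMatrix(list(partner_pool.gene_ids), mix_ids, mixes)
    votes = Counter(clf.predict(mix_matrix))

    homotypic = PairLabel(focal_type, focal_type)
    best = max(
        votes.items(),
        key=lambda kv: (kv[1], kv[0] == homotypic, _neg_lex(kv[0])),
    )[0]
    return NeighborAssignment(
        sample_id=sample_id,
        focal_type=focal_type,
        predicted_partner=best.partner_of(focal_type),
        votes=dict(votes),
        n_mixes=int(len(idx)),
    )


class _neg_lex:
    """Inverts lexicographic order so max() picks the smallest label."""

    def __init__(self, pair: PairLabel):
        self.key = str(pair)

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.key > other.key

    def __eq__(self, other) -> bool:
        return self.key == other.key


def predict_neighbors(
    singles: CountMatrix,
    labels,
    focal_type: str,
    clf: PairClassifier,
    cells: Sequence[str] | None = None,
    max_mixes: int = MAX_MIXES_DEFAULT,
    seed: int = 0,
) -> list[NeighborAssignment]:
    """Predict partners for all (or selected) focal-type cells.

    The partner pool for each cell is every *other* single cell of the same
    stage, regardless of type.
    """
    lookup = labels if isinstance(labels, Mapping) else dict(zip(singles.sample_ids, labels))
    if cells is None:
        cells = [s for s in singles.sample_ids if lookup.get(s) == focal_type]
    rng = np.random.default_rng(seed)
    out: list[NeighborAssignment] = []
    pos = {s: i for i, s in enumerate(singles.sample_ids)}
    for s in cells:
        if lookup.get(s) != focal_type:
            raise PicseqError(f"cell {s!r} is not of focal type {focal_type!r}")
        pool_ids = [t for t in singles.sample_ids if t != s]
        pool = singles.subset_samples(pool_ids)
        out.append(
            predict_neighbor(
                singles.counts[:, pos[s]],
                focal_type,
                pool,
                clf,
                max_mixes=max_mixes,
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=s,
            )
        )
    return out


@dataclass
class NeighborGeneResult:
    gene_id: str
    partner: str
    log_ratio: float
    p_value: float
    q_value: float


def neighbor_specific_genes(
    singles: NormalizedMatrix,
    assignments: Sequence[NeighborAssignment],
    focal_type: str,
    fdr_cut: float = 0.01,
) -> dict[str, list[NeighborGeneResult]]:
    """Genes marking focal cells by their predicted partner type.

    For each partner group (>= 3 cells; >= 2 groups required), focal cells
    predicted to neighbor that partner are compared against the remaining
    focal cells; reported rows pass q < fdr_cut with positive log ratio.
    """
    focal = [a for a in assignments if a.focal_type == focal_type]
    pos = {s: i for i, s in enumerate(singles.sample_ids)}
    missing = [a.sample_id for a in focal if a.sample_id not in pos]
    if missing:
        raise PicseqError(f"assignments reference unknown samples: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for a in focal:
        groups.setdefault(a.predicted_partner, []).append(pos[a.sample_id])
    groups = {p: idx for p, idx in groups.items() if len(idx) >= 3}
    if len(groups) < 2:
        raise PicseqError(
            f"focal type {focal_type!r}: need >= 2 predicted-partner groups "
            f"with >= 3 cells each"
        )
    all_idx = sorted(i for idx in groups.values() for i in idx)
    eps = singles.pseudocount
    linear = singles.linear_values()
    out: dict[str, list[NeighborGeneResult]] = {}
    for partner in sorted(groups):
        in_idx = np.array(groups[partner])
        rest = np.array([i for i in all_idx if i not in set(groups[partner])])
        p = rank_sum_scan(singles.values[:, in_idx], singles.values[:, rest])
        q = bh_fdr(p)
        lr = np.log2(
            (linear[:, in_idx].mean(axis=1) + eps) / (linear[:, rest].mean(axis=1) + eps)
        )
        rows = [
            NeighborGeneResult(singles.gene_ids[i], partner, float(lr[i]), float(p[i]), float(q[i]))
            for i in np.flatnonzero((q < fdr_cut) & (lr > 0))
        ]
        rows.sort(key=lambda r: (-r.log_ratio, r.gene_id))
        out[partner] = rows
    return out
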