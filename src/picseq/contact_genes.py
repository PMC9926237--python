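"""Contact-specific gene detection in heterotypic PICs.

A contact-specific gene is one whose expression in heterotypic PICs of a
given pair deviates from the expectation formed by combining the two member
cell types' single-cell profiles.  The expectation is operationalized as
artificial doublets: one cell of each member type, counts summed, then
normalized and log-transformed exactly like the observed PICs — this
preserves the sampling variance a rank test needs.  (A mean-profile
alternative is available behind a switch.)

Per gene, observed PICs are compared with the expected profiles by a
two-sided Wilcoxon rank-sum test; BH correction runs across genes within the
pair.  Up-regulated rows pass q < 0.01 and log ratio > 0.5, down-regulated
rows pass q < 0.01 and log ratio < -0.5, where the log ratio is
log2((mean observed + eps) / (mean expected + eps)) on the normalized linear
scale.  Only pairs with at least 10 classified PICs are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    CountMatrix,
    NormalizedMatrix,
    PairLabel,
    PicseqError,
    normalize,
)
from .stats import bh_fdr, rank_sum_scan

MIN_PICS_DEFAULT = 10
FDR_CUT_DEFAULT = 0.01
LOG_RATIO_CUT_DEFAULT = 0.5
N_EXPECTED_DEFAULT = 200


@dataclass
class ContactGeneResult:
    gene_id: str
    pair: PairLabel
    direction: str  # "up" | "down"
    log_ratio: float
    p_value: float
    q_value: float
    n_pics: int


def _indices_of_type(m: CountMatrix, labels, wanted: str) -> list[int]:
    lookup = labels if isinstance(labels, Mapping) else dict(zip(m.sample_ids, labels))
    return [i for i, s in enumerate(m.sample_ids) if lookup.get(s) == wanted]


def expected_profiles(
    singles: CountMatrix,
    labels,
    pair: PairLabel,
    n_expected: int = N_EXPECTED_DEFAULT,
    seed: int = 0,
    method: str = "artificial_doublets",
) -> NormalizedMatrix:
    """Expected combined expression for a heterotypic pair.

    ``artificial_doublets`` (default): sums of one uniformly drawn cell per
    member type, normalized/logged like PICs.  ``mean_profile``: a single
    column, the normalized sum of the two type-mean profiles.
    """
    idx_a = _indices_of_type(singles, labels, pair.type_a)
    idx_b = _indices_of_type(singles, labels, pair.type_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise PicseqError(
            f"pair {pair}: need >= 2 cells of each member type "
            f"(have {len(idx_a)} and {len(idx_b)})"
        )
    if method == "mean_profile":
        combined = singles.counts[:, idx_a].mean(axis=1) + singles.counts[:, idx_b].mean(axis=1)
        counts = np.rint(combined[:, None]).astype(np.int64)
        m = CountMatrix(list(singles.gene_ids), [f"expected_{pair}"], counts)
        return normalize(m)
    if method != "artificial_doublets":
        raise PicseqError(f"unknown expectation method {method!r}")
    rng = np.random.default_rng(seed)
    ia = rng.choice(idx_a, size=n_expected, replace=True)
    ib = rng.choice(idx_b, size=n_expected, replace=True)
    cols = singles.counts[:, ia] + singles.counts[:, ib]
    ids = [f"exp_{pair}_{k:04d}" for k in range(n_expected)]
    m = CountMatrix(list(singles.gene_ids), ids, cols)
    return normalize(m)


def detect_contact_genes(
    pics: CountMatrix,
    pic_labels,
    singles: CountMatrix,
    single_labels,
    pair: PairLabel,
    min_pics: int = MIN_PICS_DEFAULT,
    fdr_cut: float = FDR_CUT_DEFAULT,
    lr_cut: float = LOG_RATIO_CUT_DEFAULT,
    n_expected: int = N_EXPECTED_DEFAULT,
    seed: int = 0,
) -> list[ContactGeneResult]:
    """Genes over/under-expressed in heterotypic PICs of ``pair`` vs expectation.

    Returns up rows (q < fdr_cut, log ratio > lr_cut) and down rows
    (q < fdr_cut, log ratio < -lr_cut), ordered by |log ratio| descending.
    """
    if pair.is_homotypic:
        raise PicseqError(f"contact-gene detection requires a heterotypic pair, got {pair}")
    lookup = pic_labels if isinstance(pic_labels, Mapping) else dict(
        zip(pics.sample_ids, pic_labels)
    )
    keep = [s for s in pics.sample_ids if lookup.get(s) == pair]
    if len(keep) < min_pics:
        raise PicseqError(
            f"pair {pair} has {len(keep)} PICs; at least {min_pics} required"
        )
    if list(pics.gene_ids) != list(singles.gene_ids):
        raise PicseqError("PICs and singles must share the same gene universe")

    observed = normalize(pics.subset_samples(keep))
    expected = expected_profiles(
        singles, single_labels, pair, n_expected=n_expected, seed=seed
    )
    eps = observed.pseudocount
    p = rank_sum_scan(observed.values, expected.values)
    q = bh_fdr(p)
    mean_obs = observed.linear_values().mean(axis=1)
    mean_exp = expected.linear_values().mean(axis=1)
    log_ratio = np.log2((mean_obs + eps) / (mean_exp + eps))

    results: list[ContactGeneResult] = []
    for i in np.flatnonzero((q < fdr_cut) & (np.abs(log_ratio) > lr_cut)):
        results.append(
            ContactGeneResult(
                gene_id=pics.gene_ids[i],
                pair=pair,
                direction="up" if log_ratio[i] > 0 else "down",
                log_ratio=float(log_ratio[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                n_pics=len(keep),
            )
        )
    results.sort(key=lambda r: (-abs(r.log_ratio), r.gene_id))
    return results


def contact_gene_union(
    results_by_pair: Mapping[PairLabel, Sequence[ContactGeneResult]],
    focal_type: str | None = None,
) -> list[str]:
    """Union of contact genes, optionally over the pairs containing a type."""
    genes: set[str] = set()
    for pair, rows in results_by_pair.items():
        if focal_type is not None and not pair.contains(focal_type):
            continue
        genes.update(r.gene_id for r in rows)
    return sorted(genes)
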