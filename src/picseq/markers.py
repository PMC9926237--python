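"""Cell-type marker detection: one-vs-rest differential expression.

Each gene is tested per cluster by a two-sided Wilcoxon rank-sum of the
in-cluster samples against all other samples; the effect size is the log2
ratio of (pseudocounted) linear-scale group means.  Markers are genes with
q < 0.01 (Benjamini-Hochberg across genes, one family per cluster scan) and
log ratio > 0.4.  The top-k markers per cluster (by log ratio) form the
feature sets of the pair classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import NormalizedMatrix, PicseqError
from .stats import bh_fdr, rank_sum_scan

FDR_CUT_DEFAULT = 0.01
LOG_RATIO_CUT_DEFAULT = 0.4


@dataclass
class MarkerResult:
    gene_id: str
    cluster: str
    log_ratio: float
    p_value: float
    q_value: float


def _labels_to_array(m, labels) -> np.ndarray:
    if isinstance(labels, Mapping):
        missing = [s for s in m.sample_ids if s not in labels]
        if missing:
            raise PicseqError(f"labels missing for samples: {missing[:5]}")
        return np.array([labels[s] for s in m.sample_ids], dtype=object)
    labels = np.asarray(labels, dtype=object)
    if labels.size != m.n_samples:
        raise PicseqError(
            f"{labels.size} labels for {m.n_samples} samples"
        )
    return labels


def find_markers(
    m: NormalizedMatrix,
    labels: Sequence[str] | Mapping[str, str],
    fdr_cut: float = FDR_CUT_DEFAULT,
    lr_cut: float = LOG_RATIO_CUT_DEFAULT,
) -> list[MarkerResult]:
    """One-vs-rest marker scan over every cluster in ``labels``.

    Returns the rows passing ``q < fdr_cut`` and ``log_ratio > lr_cut``,
    ordered by cluster then descending log ratio.
    """
    lab = _labels_to_array(m, labels)
    clusters = sorted(set(lab))
    if len(clusters) < 2:
        raise PicseqError("need at least 2 distinct labels for a marker scan")
    for c in clusters:
        if (lab == c).sum() < 2:
            raise PicseqError(f"cluster {c!r} has fewer than 2 samples")

    eps = m.pseudocount
    linear = m.linear_values()
    values = m.values
    results: list[MarkerResult] = []
    for c in clusters:
        mask = lab == c
        p = rank_sum_scan(values[:, mask], values[:, ~mask])
        q = bh_fdr(p)
        mean_in = linear[:, mask].mean(axis=1)
        mean_out = linear[:, ~mask].mean(axis=1)
        log_ratio = np.log2((mean_in + eps) / (mean_out + eps))
        passing = np.flatnonzero((q < fdr_cut) & (log_ratio > lr_cut))
        rows = [
            MarkerResult(m.gene_ids[i], c, float(log_ratio[i]), float(p[i]), float(q[i]))
            for i in passing
        ]
        rows.sort(key=lambda r: (-r.log_ratio, r.q_value, r.gene_id))
        results.extend(rows)
    return results


def top_markers(results: Sequence[MarkerResult], k: int = 5) -> dict[str, list[str]]:
    """Per cluster, the k genes with largest log ratio among passing rows.

    Ties on log ratio break toward smaller q, then lexicographic gene id.
    Clusters with fewer than k passing genes return what they have.
    """
    if not results:
        raise PicseqError("empty marker result list")
    by_cluster: dict[str, list[MarkerResult]] = {}
    for r in results:
        by_cluster.setdefault(r.cluster, []).append(r)
    out: dict[str, list[str]] = {}
    for cluster, rows in sorted(by_cluster.items()):
        rows = sorted(rows, key=lambda r: (-r.log_ratio, r.q_value, r.gene_id))
        out[cluster] = [r.gene_id for r in rows[: max(k, 0)]]
    return out


def feature_union(top: Mapping[str, Sequence[str]]) -> list[str]:
    """Sorted union of per-cluster top marker genes (classifier features)."""
    genes: set[str] = set()
    for gene_list in top.values():
        genes.update(gene_list)
    return sorted(genes)
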