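"""Statistical primitives: Wilcoxon rank-sum, Fisher's exact test, BH FDR.

The rank-sum test uses exact enumeration over rank assignments (midranks for
ties) when the combined sample size is small, and the tie-corrected normal
approximation with continuity correction otherwise.  Group sizes in real
marker/contact scans are in the hundreds, so the approximation is the path
that matters in practice; the exact path exists so small-sample behaviour is
correct and auditable.

Two-sided exact p is defined symmetrically: the probability, under uniform
sampling of which observations belong to group one, of a rank sum at least
as far from its null mean as the observed one.  The null distribution of the
rank sum is symmetric about ``n_a (n+1) / 2`` even under ties (reflecting
every rank r to n+1-r maps the midrank multiset to itself), so this agrees
with the usual doubled-tail convention up to point-mass edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_model import PicseqError

#: Combined-size cutoff below which the rank-sum null is enumerated exactly.
EXACT_WILCOXON_MAX_N = 12


@dataclass
class TestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise PicseqError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable2x2:
    """Counts (a, b) in row one and (c, d) in row two; all non-negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise PicseqError(f"contingency entries must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise PicseqError("contingency table is empty (all margins zero)")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, observed: float) -> float:
    """Enumerate all C(n, n_a) group-one assignments of the midranks."""
    n = len(ranks)
    mean = n_a * (n + 1) / 2.0
    dev = abs(observed - mean)
    hits = 0
    total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when ``len(x) + len(y) <= EXACT_WILCOXON_MAX_N``,
    otherwise the tie-corrected normal approximation with continuity
    correction.  The statistic reported is the rank sum of ``x``.
    """
    if alternative != "two_sided":
        raise PicseqError(f"only two_sided is supported, got {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PicseqError("both samples must be non-empty")
    n_a, n_b = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:n_a].sum())
    if n_a + n_b <= EXACT_WILCOXON_MAX_N:
        p = _exact_rank_sum_p(ranks, n_a, w)
    else:
        _, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(p, 1.0))
    return TestResult(statistic=w, p_value=p, n_a=n_a, n_b=n_b)


def rank_sum_scan(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for (genes x samples) blocks.

    Vectorized large-sample path used by the marker and contact-gene scans;
    equivalent to calling :func:`wilcoxon_rank_sum` per row when both groups
    exceed the exact-path cutoff.
    """
    if x.shape[0] != y.shape[0]:
        raise PicseqError("x and y must have the same number of rows")
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise PicseqError("both groups must be non-empty")
    _, p = sps.mannwhitneyu(
        x, y, axis=1, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return np.minimum(np.asarray(p, dtype=float), 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided") -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p is the total hypergeometric probability of tables (with the observed
    margins) no more probable than the observed one.
    """
    if alternative != "two_sided":
        raise PicseqError(f"only two_sided is supported, got {alternative!r}")
    arr = table.as_array()
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    stat = float(odds) if np.isfinite(odds) else float("inf")
    return TestResult(
        statistic=stat,
        p_value=float(min(p, 1.0)),
        n_a=int(arr[0].sum()),
        n_b=int(arr[1].sum()),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise PicseqError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
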