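"""Spatial-tSNE: tSNE with injected similarity for predicted-neighbor pairs.

Standard tSNE measures similarity of cells i and j in expression space by a
Gaussian conditional probability

    p_{j|i} = exp(-||x_i - x_j||^2 / 2 sigma_i^2)
              / sum_{k != i} exp(-||x_i - x_k||^2 / 2 sigma_i^2),

with sigma_i set per cell so the conditional distribution's perplexity
(2^entropy) matches a target, then symmetrized: p_ij = (p_{j|i} + p_{i|j}) /
(2n).  The spatial variant modifies P before embedding: every cell pair
predicted to be in-tissue neighbors receives the maximal pairwise
probability, and P is renormalized.  Gradient descent on KL(P || Q) with a
Student-t low-dimensional kernel then pulls predicted neighbors to the
border between their two clusters without disturbing the relative layout of
the remaining cells.

Cell-level neighbor edges are derived from per-cell partner-type
predictions: in ``mutual`` mode cells i and j are joined when each predicts
the other's type (types differing); ``one_sided`` requires only i's
prediction to match j's type or vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import PicseqError
from .neighbor_predictor import NeighborAssignment

PERPLEXITY_DEFAULT = 30.0
_ENTROPY_TOL = 1e-5
_MAX_BISECTIONS = 50


# ---------------------------------------------------------------------------
# Affinities
# ---------------------------------------------------------------------------

@dataclass
class AffinityMatrix:
    P: np.ndarray
    perplexity: float
    sigmas: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.P.shape[0]


def conditional_affinities(X: np.ndarray, perplexity: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic conditional matrix p_{j|i} and the fitted sigmas.

    Each row's bandwidth is set by bisection on beta = 1/(2 sigma^2) until
    2^H(p_.|i) matches the perplexity.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise PicseqError("need at least 3 cells")
    if not perplexity < n - 1:
        raise PicseqError(f"perplexity {perplexity} must be < n-1 = {n - 1}")
    sq = (X ** 2).sum(axis=1)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    target = np.log2(perplexity)
    P = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        d = np.delete(D[i], i)
        beta, lo, hi = 1.0, 0.0, np.inf
        for _ in range(_MAX_BISECTIONS):
            w = np.exp(-d * beta)
            s = w.sum()
            if s <= 0:
                h = 0.0
                p = w
            else:
                p = w / s
                nz = p > 0
                h = -(p[nz] * np.log2(p[nz])).sum()
            if abs(h - target) < _ENTROPY_TOL:
                break
            if h > target:  # too flat -> narrow the Gaussian
                lo = beta
                beta = beta * 2.0 if hi == np.inf else (beta + hi) / 2.0
            else:
                hi = beta
                beta = (lo + beta) / 2.0
        row = np.zeros(n)
        row[np.arange(n) != i] = p
        P[i] = row
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return P, sigmas


def pairwise_affinities(
    X: np.ndarray,
    perplexity: float = PERPLEXITY_DEFAULT,
    sample_ids: Sequence[str] | None = None,
) -> AffinityMatrix:
    """Symmetrized tSNE affinities with per-cell perplexity calibration."""
    cond, sigmas = conditional_affinities(X, perplexity)
    n = cond.shape[0]
    P = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise PicseqError("sample_ids length mismatch")
    return AffinityMatrix(P=P, perplexity=float(perplexity), sigmas=sigmas, sample_ids=ids)


# ---------------------------------------------------------------------------
# Neighbor graph and injection
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    edges: set[tuple[str, str]]  # canonically ordered id pairs
    mode: str = "mutual"


def build_neighbor_graph(
    assignments: Sequence[NeighborAssignment],
    labels: Mapping[str, str],
    mode: str = "mutual",
) -> NeighborGraph:
    """Cell-pair edges implied by per-cell partner-type predictions.

    ``mutual``: edge (i, j) iff type(i) != type(j), i predicts type(j) and j
    predicts type(i).  ``one_sided`` drops the second prediction requirement.
    Edges only join cells of different types; no self-edges.
    """
    if mode not in ("mutual", "one_sided"):
        raise PicseqError(f"unknown mode {mode!r}")
    pred = {a.sample_id: a.predicted_partner for a in assignments}
    cells = [a.sample_id for a in assignments]
    edges: set[tuple[str, str]] = set()
    for i, ci in enumerate(cells):
        for cj in cells[i + 1:]:
            ti, tj = labels[ci], labels[cj]
            if ti == tj:
                continue
            fwd = pred[ci] == tj
            rev = pred[cj] == ti
            if (fwd and rev) or (mode == "one_sided" and (fwd or rev)):
                edges.add((min(ci, cj), max(ci, cj)))
    return NeighborGraph(edges=edges, mode=mode)


def inject_neighbor_edges(aff: AffinityMatrix, g: NeighborGraph) -> AffinityMatrix:
    """Set every neighbor edge to the maximal pairwise probability, renormalize."""
    pos = {s: i for i, s in enumerate(aff.sample_ids)}
    missing = [e for e in g.edges if e[0] not in pos or e[1] not in pos]
    if missing:
        raise PicseqError(f"graph references cells outside the affinity matrix: {missing[:3]}")
    P = aff.P.copy()
    if g.edges:
        pmax = P.max()
        for a, b in g.edges:
            i, j = pos[a], pos[b]
            P[i, j] = P[j, i] = pmax
        P /= P.sum()
    return AffinityMatrix(P=P, perplexity=aff.perplexity, sigmas=aff.sigmas.copy(),
                          sample_ids=list(aff.sample_ids))


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    coords: np.ndarray
    kl_divergence: float
    seed: int
    iterations: int
    sample_ids: list[str] = field(default_factory=list)


_EPS = 1e-12


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    return float((P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))).sum())


def tsne_embed(
    aff: AffinityMatrix,
    iterations: int = 1000,
    seed: int = 0,
    learning_rate: float = 200.0,
    early_exaggeration: float = 12.0,
    exaggeration_iters: int = 250,
) -> Embedding:
    """KL(P || Q) gradient descent with a Student-t kernel in 2D.

    Standard schedule: early exaggeration for the first ``exaggeration_iters``
    iterations, momentum 0.5 switching to 0.8 at iteration 250, adaptive
    per-coordinate gains, seeded small-variance Gaussian initialization.
    """
    P = np.maximum(aff.P, 0.0)
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise PicseqError(f"affinity matrix sums to {total}, expected 1")
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    P_run = P * early_exaggeration

    kl = np.inf
    for it in range(iterations):
        if it == min(exaggeration_iters, iterations):
            # end of exaggeration: restart optimizer state for the new objective
            P_run = P
            dY[:] = 0.0
            gains[:] = 1.0
        sq = (Y ** 2).sum(axis=1)
        num = 1.0 / (1.0 + np.maximum(sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T, 0.0))
        np.fill_diagonal(num, 0.0)
        Q = num / max(num.sum(), _EPS)
        PQn = (P_run - Q) * num
        grad = 4.0 * (np.diag(PQn.sum(axis=1)) - PQn) @ Y
        if not np.all(np.isfinite(grad)):
            raise PicseqError(f"non-finite tSNE gradient at iteration {it}")
        momentum = 0.5 if it < 250 else 0.8
        inc = dY * grad < 0.0  # step still descending this coordinate
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dY = momentum * dY - learning_rate * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)
    sq = (Y ** 2).sum(axis=1)
    num = 1.0 / (1.0 + np.maximum(sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T, 0.0))
    np.fill_diagonal(num, 0.0)
    Q = num / max(num.sum(), _EPS)
    kl = _kl(P, Q)
    return Embedding(coords=Y, kl_divergence=kl, seed=seed, iterations=iterations,
                     sample_ids=list(aff.sample_ids))


def embed_with_neighbors(
    X: np.ndarray,
    sample_ids: Sequence[str],
    assignments: Sequence[NeighborAssignment],
    labels: Mapping[str, str],
    perplexity: float = PERPLEXITY_DEFAULT,
    mode: str = "mutual",
    iterations: int = 1000,
    seed: int = 0,
) -> Embedding:
    """High-level wrapper: affinities -> neighbor graph -> injection -> embed."""
    aff = pairwise_affinities(X, perplexity, sample_ids)
    graph = build_neighbor_graph(assignments, labels, mode)
    return tsne_embed(inject_neighbor_edges(aff, graph), iterations=iterations, seed=seed)


def pca_reduce(values: np.ndarray, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """Center and project (samples x features) onto the top principal axes."""
    from sklearn.decomposition import PCA

    k = int(min(n_components, values.shape[0] - 1, values.shape[1]))
    return PCA(n_components=k, random_state=seed).fit_transform(values)
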