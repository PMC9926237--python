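"""Seeded generator of synthetic embryos: singles, PICs, and ground truth.

The generator emulates the statistical structure the rest of the package
assumes about plate-based embryo data:

* several cell types, each with a block of marker genes elevated by a
  constant fold over a shared baseline;
* negative-binomial (UMI-like, overdispersed) counts, with per-cell library
  depth drawn uniformly from a range and imposed by binomial thinning
  (thinning preserves the negative-binomial family, so null genes stay
  NB-distributed at the thinned mean);
* PICs formed as elementwise sums of two emitted single cells — homotypic
  from two distinct same-type cells, heterotypic from one cell per member
  type;
* contact-specific induction: designated non-marker genes whose
  contributions are multiplied by a fold in heterotypic PICs of a designated
  pair (applied to both members' realized counts, then rounded, so
  conservation is exactly checkable from the recorded members);
* planted neighbor identity: each single cell of a type participating in a
  contact pair is assigned a partner type (heterotypic with a configurable
  probability, otherwise its own type); heterotypic-planted cells carry an
  attenuated version of the pair's contact induction (half the PIC induction
  on the log scale) in their own transcriptome — the signal the neighbor
  predictor relies on.

PIC members are drawn from the homotypic-planted cells of each type so a
cell's own planted induction never compounds with the PIC-level induction.

What it does not emulate: tissue geometry, batch effects, stage structure
(one stage suffices; multiple stages are a config loop), gene-gene
correlation beyond the type blocks, and ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import CountMatrix, PairLabel, PicseqError, SampleAnnotation


@dataclass(frozen=True)
class ContactPairSpec:
    """One heterotypic pair with planted contact-specific genes."""

    pair: PairLabel
    n_genes: int
    induction_fold: float

    def __post_init__(self) -> None:
        if self.pair.is_homotypic:
            raise PicseqError(f"contact pair {self.pair} must be heterotypic")
        if self.induction_fold < 1:
            raise PicseqError("induction_fold must be >= 1")


@dataclass
class SimulationConfig:
    n_types: int = 4
    type_names: tuple[str, ...] = ("NP", "DE", "FG", "NC")
    n_genes: int = 2000
    cells_per_type: int = 150
    markers_per_type: int = 10
    marker_fold: float = 4.0
    contact_pairs: tuple[ContactPairSpec, ...] = ()
    pics_per_pair: int = 30
    base_mean: float = 20.0
    dispersion: float = 2.0
    depth_range: tuple[int, int] = (2000, 20000)
    heterotypic_neighbor_prob: float = 0.15
    stage: str = "E8.5"
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.type_names) != self.n_types:
            raise PicseqError("type_names must list n_types names")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise PicseqError("more marker genes than genes")
        n_contact = sum(cp.n_genes for cp in self.contact_pairs)
        if self.markers_per_type * self.n_types + n_contact > self.n_genes:
            raise PicseqError("marker and contact gene blocks exceed the gene universe")
        for cp in self.contact_pairs:
            if not (cp.pair.contains(cp.pair.type_a) and cp.pair.type_a in self.type_names
                    and cp.pair.type_b in self.type_names):
                raise PicseqError(f"contact pair {cp.pair} uses unknown types")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise PicseqError("depth_range must satisfy 0 < min <= max")
        if not 0 <= self.heterotypic_neighbor_prob <= 0.5:
            raise PicseqError("heterotypic_neighbor_prob must be in [0, 0.5]")
        # heterotypic prob applies per contact partner; total must stay <= 1
        for t in self.type_names:
            k = sum(1 for cp in self.contact_pairs if cp.pair.contains(t))
            if k * self.heterotypic_neighbor_prob > 1:
                raise PicseqError(f"neighbor probabilities for type {t} exceed 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the matrices."""

    cell_types: dict[str, str]
    pic_members: dict[str, tuple[str, str]]
    pic_labels: dict[str, PairLabel]
    marker_genes: dict[str, list[str]]
    contact_genes: dict[PairLabel, list[str]]
    neighbor_partner: dict[str, str]
    pic_induction: dict[str, dict[str, float]] = field(default_factory=dict)


def default_config() -> SimulationConfig:
    """The reference study conditions used throughout the test-bench.

    Four types, 2,000 genes, 150 cells per type, 10 markers per type at
    4-fold, two contact pairs (NP+DE: 8 genes, NP+NC: 6 genes, both 3-fold),
    30 PICs per unordered pair, seed 1.
    """
    return SimulationConfig(
        contact_pairs=(
            ContactPairSpec(PairLabel("NP", "DE"), 8, 3.0),
            ContactPairSpec(PairLabel("NP", "NC"), 6, 3.0),
        ),
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB with var = mu + mu^2/theta (gamma-Poisson parameterization)."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _thin_to_depth(
    rng: np.random.Generator, counts: np.ndarray, depths: np.ndarray
) -> np.ndarray:
    """Binomial thinning of each column toward its target depth."""
    totals = counts.sum(axis=0)
    q = np.minimum(depths / np.maximum(totals, 1), 1.0)
    return rng.binomial(counts, q[None, :])


def simulate_embryo(cfg: SimulationConfig):
    """Generate (singles, single_annotations, pics, pic_annotations, truth).

    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]

    # gene roles: markers first, contact genes next, the rest null
    marker_genes: dict[str, list[str]] = {}
    cursor = 0
    for t in cfg.type_names:
        marker_genes[t] = gene_ids[cursor: cursor + cfg.markers_per_type]
        cursor += cfg.markers_per_type
    contact_genes: dict[PairLabel, list[str]] = {}
    for cp in cfg.contact_pairs:
        contact_genes[cp.pair] = gene_ids[cursor: cursor + cp.n_genes]
        cursor += cp.n_genes

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    type_weights: dict[str, np.ndarray] = {}
    for t in cfg.type_names:
        w = np.full(cfg.n_genes, cfg.base_mean)
        w[[gene_pos[g] for g in marker_genes[t]]] *= cfg.marker_fold
        type_weights[t] = w

    # planted neighbor partner per single cell
    partners_of: dict[str, list[ContactPairSpec]] = {
        t: [cp for cp in cfg.contact_pairs if cp.pair.contains(t)] for t in cfg.type_names
    }
    cell_types: dict[str, str] = {}
    neighbor_partner: dict[str, str] = {}
    sample_ids: list[str] = []
    cell_weight: list[np.ndarray] = []
    for t in cfg.type_names:
        cps = partners_of[t]
        for i in range(cfg.cells_per_type):
            sid = f"{t}_c{i:03d}"
            sample_ids.append(sid)
            cell_types[sid] = t
            partner = t
            w = type_weights[t]
            u = rng.random()
            for j, cp in enumerate(cps):
                if j * cfg.heterotypic_neighbor_prob <= u < (j + 1) * cfg.heterotypic_neighbor_prob:
                    partner = cp.pair.partner_of(t)
                    # attenuated induction: half the PIC induction on log scale
                    w = w.copy()
                    idx = [gene_pos[g] for g in contact_genes[cp.pair]]
                    w[idx] *= cp.induction_fold ** 0.5
                    break
            neighbor_partner[sid] = partner
            cell_weight.append(w)

    n_cells = len(sample_ids)
    means = np.stack(cell_weight, axis=1)  # genes x cells
    raw = _nb_draw(rng, means, cfg.dispersion)
    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=n_cells)
    counts = _thin_to_depth(rng, raw, depths)
    singles = CountMatrix(gene_ids, sample_ids, counts)
    single_annotations = [
        SampleAnnotation(s, cfg.stage, "single", cell_types[s]) for s in sample_ids
    ]

    # PICs: members drawn from homotypic-planted cells of each type
    homotypic_pool = {
        t: [s for s in sample_ids if cell_types[s] == t and neighbor_partner[s] == t]
        for t in cfg.type_names
    }
    for t, pool in homotypic_pool.items():
        if len(pool) < 2:
            raise PicseqError(f"type {t} has too few cells to build PICs")
    induction_of = {cp.pair: cp.induction_fold for cp in cfg.contact_pairs}
    sample_col = {s: i for i, s in enumerate(sample_ids)}

    pic_ids: list[str] = []
    pic_cols: list[np.ndarray] = []
    pic_members: dict[str, tuple[str, str]] = {}
    pic_labels: dict[str, PairLabel] = {}
    pic_induction: dict[str, dict[str, float]] = {}
    pairs = [
        PairLabel(cfg.type_names[i], cfg.type_names[j])
        for i in range(cfg.n_types)
        for j in range(i, cfg.n_types)
    ]
    for pair in sorted(pairs):
        fold = induction_of.get(pair, 1.0)
        idx = [gene_pos[g] for g in contact_genes.get(pair, [])]
        for k in range(cfg.pics_per_pair):
            if pair.is_homotypic:
                a, b = rng.choice(homotypic_pool[pair.type_a], size=2, replace=False)
            else:
                a = rng.choice(homotypic_pool[pair.type_a])
                b = rng.choice(homotypic_pool[pair.type_b])
            va = counts[:, sample_col[a]].astype(float).copy()
            vb = counts[:, sample_col[b]].astype(float).copy()
            if idx and fold != 1.0:
                va[idx] *= fold
                vb[idx] *= fold
            pic = np.rint(va + vb).astype(np.int64)
            pid = f"pic_{pair.type_a}+{pair.type_b}_{k:03d}"
            pic_ids.append(pid)
            pic_cols.append(pic)
            pic_members[pid] = (str(a), str(b))
            pic_labels[pid] = pair
            pic_induction[pid] = {gene_ids[i]: fold for i in idx} if fold != 1.0 else {}

    pics = CountMatrix(gene_ids, pic_ids, np.stack(pic_cols, axis=1))
    pic_annotations = [
        SampleAnnotation(p, cfg.stage, "pic", pic_labels[p]) for p in pic_ids
    ]
    truth = SyntheticTruth(
        cell_types=cell_types,
        pic_members=pic_members,
        pic_labels=pic_labels,
        marker_genes=marker_genes,
        contact_genes=contact_genes,
        neighbor_partner=neighbor_partner,
        pic_induction=pic_induction,
    )
    return singles, single_annotations, pics, pic_annotations, truth
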