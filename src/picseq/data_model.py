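"""Core containers for UMI count data and sample annotations.

Everything downstream (QC, marker scans, pair classification, contact-gene
detection, neighbor prediction, spatial-tSNE) consumes these types.  Counts
are kept as dense integer arrays (genes x samples); the studies this package
targets are plate-based (MARS-seq scale, thousands of cells), where dense
storage is comfortable.

Normalization is per-sample relative frequency scaled to a fixed factor,
optionally followed by ``log2(x + pseudocount)``.  PIC (physically
interacting cells) libraries carry roughly two cells' worth of molecules, so
every comparison between PICs and single cells must be depth-invariant;
normalization is therefore applied before any cross-kind statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger("picseq")

#: Column-sum target used throughout unless overridden.
DEFAULT_SCALE_FACTOR = 10_000.0
#: Pseudocount for the log2 transform and for log-ratio denominators.
DEFAULT_PSEUDOCOUNT = 1.0


class PicseqError(ValueError):
    """Raised for malformed inputs and violated preconditions."""


# ---------------------------------------------------------------------------
# Pair labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class PairLabel:
    """Unordered pair of cell-type names; ``(A, B) == (B, A)``.

    Stored in canonical (lexicographically sorted) order, so pair labels can
    be used as dict keys and compared directly.  A homotypic pair has both
    members equal.
    """

    type_a: str
    type_b: str

    def __post_init__(self) -> None:
        a, b = sorted((self.type_a, self.type_b))
        object.__setattr__(self, "type_a", a)
        object.__setattr__(self, "type_b", b)

    @property
    def is_homotypic(self) -> bool:
        return self.type_a == self.type_b

    def partner_of(self, focal_type: str) -> str:
        """The other member, or ``focal_type`` itself for a homotypic pair."""
        if focal_type == self.type_a:
            return self.type_b
        if focal_type == self.type_b:
            return self.type_a
        raise PicseqError(f"{focal_type!r} is not a member of {self}")

    def contains(self, cell_type: str) -> bool:
        return cell_type in (self.type_a, self.type_b)

    def __str__(self) -> str:  # serialized as "A+B"
        return f"{self.type_a}+{self.type_b}"

    @classmethod
    def parse(cls, text: str) -> "PairLabel":
        parts = text.split("+")
        if len(parts) != 2 or not all(parts):
            raise PicseqError(f"cannot parse pair label {text!r}")
        return cls(parts[0], parts[1])


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """Per-sample metadata: developmental stage, kind, and label.

    ``kind`` is ``"single"`` or ``"pic"``.  For singles the label is a cell
    type string; for PICs it is a :class:`PairLabel` (possibly ``None``
    before classification).
    """

    sample_id: str
    stage: str = ""
    kind: str = "single"
    label: str | PairLabel | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "pic"):
            raise PicseqError(f"kind must be 'single' or 'pic', got {self.kind!r}")
        if self.kind == "single" and isinstance(self.label, PairLabel):
            raise PicseqError(f"single sample {self.sample_id!r} has a pair label")
        if self.kind == "pic" and isinstance(self.label, str):
            self.label = PairLabel.parse(self.label)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a TSV with columns sample_id, stage, kind, label."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "stage", "kind", "label"}
    missing = required - set(df.columns)
    if missing:
        raise PicseqError(f"annotation file {path} lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        label: str | PairLabel | None = row.label or None
        if label is not None and row.kind == "pic":
            label = PairLabel.parse(label)
        out.append(SampleAnnotation(row.sample_id, row.stage, row.kind, label))
    return out


def write_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = [
        (a.sample_id, a.stage, a.kind, "" if a.label is None else str(a.label))
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["sample_id", "stage", "kind", "label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise PicseqError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise PicseqError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise PicseqError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            g, s = np.unravel_index(int(np.argmin(self.counts)), self.counts.shape)
            raise PicseqError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def totals(self) -> np.ndarray:
        """Per-sample total UMI counts."""
        return self.counts.sum(axis=0)

    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Samples by id list or boolean mask; order preserved."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return CountMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.counts[:, idx].copy(),
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise PicseqError(f"genes absent from matrix: {missing}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix(list(genes), list(self.sample_ids), self.counts[idx, :].copy())

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]


@dataclass
class NormalizedMatrix:
    """Relative-frequency-scaled (and optionally log2) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_factor: float = DEFAULT_SCALE_FACTOR
    log_transformed: bool = False
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def linear_values(self) -> np.ndarray:
        """Values on the linear (pre-log) scale."""
        if not self.log_transformed:
            return self.values
        return np.exp2(self.values) - self.pseudocount

    def subset_genes(self, genes: Sequence[str]) -> "NormalizedMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise PicseqError(f"genes absent from matrix: {missing}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return NormalizedMatrix(
            list(genes), list(self.sample_ids), self.values[idx, :].copy(),
            self.scale_factor, self.log_transformed, self.pseudocount,
        )


def normalize(
    m: CountMatrix,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    log_transform: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NormalizedMatrix:
    """Depth-normalize each sample to ``scale_factor`` total, optionally log2.

    Raises on zero-total samples (their relative frequencies are undefined).
    """
    totals = m.totals().astype(float)
    if np.any(totals <= 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise PicseqError(f"zero-total samples cannot be normalized: {bad}")
    values = m.counts / totals[None, :] * scale_factor
    if log_transform:
        values = np.log2(values + pseudocount)
    return NormalizedMatrix(
        list(m.gene_ids), list(m.sample_ids), values,
        scale_factor, log_transform, pseudocount,
    )


def normalize_vectors(
    counts: np.ndarray,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    log_transform: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Column-wise normalization of a raw (genes x samples) array."""
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise PicseqError("zero-total column in normalize_vectors")
    values = counts / totals[None, :] * scale_factor
    if log_transform:
        values = np.log2(values + pseudocount)
    return values


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str = "dense_tsv") -> CountMatrix:
    """Read a count matrix.

    ``dense_tsv``: genes as rows, header row of sample ids, first column of
    gene ids.  ``mtx_triplet``: a MatrixMarket coordinate file with companion
    ``genes.tsv`` and ``barcodes.tsv`` (one id per line) in the same
    directory.
    """
    path = Path(path)
    if not path.exists():
        raise PicseqError(f"no such file: {path}")
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        if np.issubdtype(counts.dtype, np.floating) and not np.allclose(
            counts, np.round(counts)
        ):
            raise PicseqError(f"non-integer entries in {path}")
        return CountMatrix(
            [str(g) for g in df.index], [str(s) for s in df.columns], counts
        )
    if format == "mtx_triplet":
        mat = mmread(path)
        counts = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        if not np.allclose(counts, np.round(counts)):
            raise PicseqError(f"non-integer entries in {path}")
        genes = _read_id_file(path.parent / "genes.tsv", counts.shape[0], "gene")
        barcodes = _read_id_file(path.parent / "barcodes.tsv", counts.shape[1], "sample")
        return CountMatrix(genes, barcodes, counts.astype(np.int64))
    raise PicseqError(f"unknown format {format!r}")


def _read_id_file(path: Path, expected: int, what: str) -> list[str]:
    if not path.exists():
        raise PicseqError(f"missing companion file {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if len(ids) != expected:
        raise PicseqError(
            f"{path} lists {len(ids)} {what} ids but the matrix has {expected}"
        )
    return ids


def write_counts(m: CountMatrix, path: str | Path, format: str = "dense_tsv") -> None:
    path = Path(path)
    if format == "dense_tsv":
        pd.DataFrame(m.counts, index=m.gene_ids, columns=m.sample_ids).to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        mmwrite(path, coo_matrix(m.counts), field="integer")
        (path.parent / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise PicseqError(f"unknown format {format!r}")
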