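"""Single-cell rules: QC, leukemic-cell marker filter, gene-set scoring,
cell-cycle phase assignment, cycling fraction, and Shannon lineage diversity.

Phase assignment follows a pooled-cutoff rule: cells are scored for G1/S and
G2/M gene sets as the average log2 of library-size-normalized expression, a
global cutoff per gene set is the mean + 1 SD of scores pooled across all
samples, and each cell is G0 (below both cutoffs), G1/S (strictly above the
G1/S cutoff but not the G2/M cutoff) or G2/M (strictly above the G2/M
cutoff).  "Exceeding" a cutoff is strict, so ties sit below.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEUKEMIC_REQUIRED = "DNTT"
LEUKEMIC_EXCLUDE_IF_NO_DNTT = ("LYZ", "GZMH", "IL32")  # mono/gran, NK, NK/T
LEUKEMIC_EXCLUDE_ALWAYS = ("CD3E", "CD3G", "CD8A")     # T cells


class Phase(str, Enum):
    G0 = "G0"
    G1S = "G1S"
    G2M = "G2M"


@dataclass
class PhaseCall:
    cell: str
    score_g1s: float
    score_g2m: float
    phase: Phase


@dataclass
class DiversityResult:
    sample_id: str
    proportions: dict
    shannon_h: float


@dataclass
class CellMatrix:
    """Dense UMI count matrix, cells x genes."""

    genes: list
    cells: list
    counts: np.ndarray  # shape (n_cells, n_genes), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape must be (n_cells, n_genes)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        self._gene_idx = {g: i for i, g in enumerate(self.genes)}

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def gene_index(self, genes: Iterable[str]) -> list[int]:
        return [self._gene_idx[g] for g in genes if g in self._gene_idx]

    def subset_cells(self, keep: Sequence[str]) -> "CellMatrix":
        keep_set = set(keep)
        idx = [i for i, c in enumerate(self.cells) if c in keep_set]
        return CellMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[idx],
        )

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_mtx_dir(cls, path: Union[str, Path]) -> "CellMatrix":
        """Read a triplet bundle: matrix.mtx (genes x cells, CellRanger
        orientation), genes.tsv, barcodes.tsv."""
        from scipy.io import mmread

        path = Path(path)
        mat = mmread(path / "matrix.mtx").toarray().T  # -> cells x genes
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        return cls(genes=genes, cells=cells, counts=mat.astype(int))

    def to_mtx_dir(self, path: Union[str, Path]) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), csr_matrix(self.counts.T))
        pd.Series(self.genes).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(self.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)

    @classmethod
    def from_dense_tsv(cls, path: Union[str, Path]) -> "CellMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(genes=df.columns.tolist(), cells=df.index.tolist(),
                   counts=df.to_numpy().astype(int))


def read_gmt(path: Union[str, Path]) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_annotations(path: Union[str, Path]) -> pd.DataFrame:
    """Two/three-column TSV: barcode, annotation[, sample_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df


def qc_filter(
    matrix: CellMatrix,
    mito_genes: Sequence[str],
    ribo_genes: Sequence[str],
    max_ribo_frac: float = 0.60,
    max_mito_frac: float = 0.30,
    min_genes: int = 1000,
) -> list[str]:
    """Return barcodes passing QC: ribosomal fraction <= 60%, mitochondrial
    fraction <= 30%, and at least ``min_genes`` expressed genes (cells with
    *fewer* than the floor are removed, so the boundary cell is retained)."""
    if not list(mito_genes) or not list(ribo_genes):
        raise ValueError("mito_genes and ribo_genes must be nonempty")
    totals = matrix.totals.astype(float)
    totals_safe = np.where(totals > 0, totals, 1.0)
    mito = matrix.counts[:, matrix.gene_index(mito_genes)].sum(axis=1) / totals_safe
    ribo = matrix.counts[:, matrix.gene_index(ribo_genes)].sum(axis=1) / totals_safe
    n_expressed = (matrix.counts > 0).sum(axis=1)
    keep = (ribo <= max_ribo_frac) & (mito <= max_mito_frac) & (n_expressed >= min_genes)
    return [c for c, k in zip(matrix.cells, keep) if k]


def leukemic_filter(
    matrix: CellMatrix,
    cluster_labels: Mapping[str, object],
    cluster_removal_frac: float = 0.60,
) -> list[str]:
    """Retain leukemic-like cells by lineage-marker exclusion.

    A cell is flagged non-leukemic when it lacks DNTT but expresses LYZ, GZMH
    or IL32, or when it expresses CD3E, CD3G or CD8A ("expressed" = count > 0).
    Flagged cells are removed; when more than ``cluster_removal_frac`` of a
    cluster is flagged the whole cluster is removed.  Marker genes missing
    from the matrix are treated as unexpressed (with a warning).
    """

    def _expr(gene: str) -> np.ndarray:
        idx = matrix.gene_index([gene])
        if not idx:
            logger.warning("leukemic_filter: marker gene %s absent from matrix", gene)
            return np.zeros(len(matrix.cells), dtype=bool)
        return matrix.counts[:, idx[0]] > 0

    dntt = _expr(LEUKEMIC_REQUIRED)
    lineage = np.zeros(len(matrix.cells), dtype=bool)
    for g in LEUKEMIC_EXCLUDE_IF_NO_DNTT:
        lineage |= _expr(g)
    tcell = np.zeros(len(matrix.cells), dtype=bool)
    for g in LEUKEMIC_EXCLUDE_ALWAYS:
        tcell |= _expr(g)
    flagged = (~dntt & lineage) | tcell

    removed_clusters = set()
    labels = np.array([cluster_labels.get(c) for c in matrix.cells], dtype=object)
    for cl in set(labels.tolist()):
        if cl is None:
            continue
        in_cl = labels == cl
        if flagged[in_cl].mean() > cluster_removal_frac:
            removed_clusters.add(cl)
    keep = ~flagged & ~np.isin(labels, list(removed_clusters))
    return [c for c, k in zip(matrix.cells, keep) if k]


def normalize_log2(matrix: CellMatrix, scale: Optional[float] = None) -> np.ndarray:
    """Library-size normalization then log2(x+1): counts / cell total x scale
    (default: median cell total)."""
    totals = matrix.totals.astype(float)
    if scale is None:
        scale = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    totals_safe = np.where(totals > 0, totals, 1.0)
    norm = matrix.counts / totals_safe[:, None] * scale
    return np.log2(norm + 1.0)


def score_gene_set(
    matrix: CellMatrix,
    gene_set: Sequence[str],
    lognorm: Optional[np.ndarray] = None,
    scale: Optional[float] = None,
) -> np.ndarray:
    """Per-cell score: mean log2 normalized expression over gene-set members
    present in the matrix."""
    idx = matrix.gene_index(gene_set)
    if not idx:
        raise ValueError("no gene-set member present in matrix")
    if lognorm is None:
        lognorm = normalize_log2(matrix, scale=scale)
    return lognorm[:, idx].mean(axis=1)


def phase_cutoffs(g1s_scores: np.ndarray, g2m_scores: np.ndarray) -> tuple[float, float]:
    """Global cutoffs: mean + 1 sample SD of scores pooled across all cells."""
    g1s_scores = np.asarray(g1s_scores, dtype=float)
    g2m_scores = np.asarray(g2m_scores, dtype=float)
    if g1s_scores.size < 2:
        raise ValueError("phase cutoffs require at least 2 cells")
    return (
        float(g1s_scores.mean() + g1s_scores.std(ddof=1)),
        float(g2m_scores.mean() + g2m_scores.std(ddof=1)),
    )


def assign_phase(
    g1s_scores: Sequence[float],
    g2m_scores: Sequence[float],
    cells: Optional[Sequence[str]] = None,
    cutoffs: Optional[tuple[float, float]] = None,
) -> list[PhaseCall]:
    """Assign G0 / G1S / G2M per cell from pooled mean+1SD cutoffs.

    Below both cutoffs -> G0; strictly above the G1/S cutoff but not above
    the G2/M cutoff -> G1S; strictly above the G2/M cutoff -> G2M.  Scores
    must be pooled across all samples before cutoffs are computed.
    """
    g1s = np.asarray(g1s_scores, dtype=float)
    g2m = np.asarray(g2m_scores, dtype=float)
    if g1s.shape != g2m.shape:
        raise ValueError("score vectors must align")
    if cutoffs is None:
        cutoffs = phase_cutoffs(g1s, g2m)
    cut_g1s, cut_g2m = cutoffs
    if cells is None:
        cells = [f"cell{i}" for i in range(g1s.size)]
    calls = []
    for cell, s1, s2 in zip(cells, g1s, g2m):
        if s2 > cut_g2m:
            phase = Phase.G2M
        elif s1 > cut_g1s:
            phase = Phase.G1S
        else:
            phase = Phase.G0
        calls.append(PhaseCall(cell=cell, score_g1s=float(s1), score_g2m=float(s2), phase=phase))
    return calls


def cycling_fraction(phase_calls: Sequence[PhaseCall]) -> float:
    """Fraction of cells in non-G0 phases."""
    if not phase_calls:
        raise ValueError("cycling_fraction requires at least one cell")
    n_cyc = sum(c.phase is not Phase.G0 for c in phase_calls)
    return n_cyc / len(phase_calls)


def shannon_index(annotation_counts: Mapping[str, float], base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero annotation
    proportions (natural log by default)."""
    counts = np.array([c for c in annotation_counts.values() if c > 0], dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("shannon_index requires at least one nonzero count")
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def diversity_by_sample(
    annotations: pd.DataFrame,
    sample_col: str = "sample_id",
    label_col: str = "annotation",
    base: float = math.e,
) -> list[DiversityResult]:
    out = []
    for sample, grp in annotations.groupby(sample_col):
        counts = grp[label_col].value_counts().to_dict()
        total = sum(counts.values())
        out.append(
            DiversityResult(
                sample_id=str(sample),
                proportions={k: v / total for k, v in counts.items()},
                shannon_h=shannon_index(counts, base=base),
            )
        )
    return out
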