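"""Collapse gene-tagged reads into a UMI-filtered digital expression matrix.

The matrix type is a thin genes x cells wrapper around a dense integer numpy
array plus ordered identifier lists; column sums and per-cell detected-gene
counts are derived, never stored independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "GeneTaggedRead",
    "DigitalExpressionMatrix",
    "NormalizedMatrix",
    "count_umis",
    "count_reads",
    "filter_cells",
    "normalize",
    "mito_fraction",
    "read_tagged_tsv",
    "read_tagged_sam",
]


@dataclass(frozen=True)
class GeneTaggedRead:
    cell_barcode: str
    umi: str
    gene: str
    pool: str | None = None


@dataclass
class DigitalExpressionMatrix:
    """Genes x cells UMI (or read) count matrix with ordered identifiers."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # shape (n_genes, n_cells), integer >= 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if self.counts.size and (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def genes_per_cell(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)

    def write_mtx(self, outdir) -> None:
        """MatrixMarket triplet: matrix.mtx + genes.tsv + barcodes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "matrix.mtx", scipy.sparse.coo_matrix(self.counts))
        pd.Series(self.genes).to_csv(outdir / "genes.tsv", index=False, header=False)
        pd.Series(self.cells).to_csv(outdir / "barcodes.tsv", index=False, header=False)

    @classmethod
    def read_mtx(cls, indir) -> "DigitalExpressionMatrix":
        indir = Path(indir)
        counts = scipy.io.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
        genes = pd.read_csv(indir / "genes.tsv", header=None)[0].tolist()
        cells = pd.read_csv(indir / "barcodes.tsv", header=None)[0].tolist()
        return cls(genes=genes, cells=cells, counts=counts)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DigitalExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=df.index.tolist(),
            cells=df.columns.tolist(),
            counts=df.to_numpy(dtype=np.int64),
        )


def _hamming1_components(umis: list[str]) -> int:
    """Number of connected components of the Hamming-distance-1 graph."""
    n = len(umis)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        ui = umis[i]
        for j in range(i + 1, n):
            uj = umis[j]
            diff = 0
            for a, b in zip(ui, uj):
                if a != b:
                    diff += 1
                    if diff > 1:
                        break
            if diff <= 1:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})


def _collect(reads: Iterable[GeneTaggedRead], whitelist: list[str] | None):
    """Gather per-(cell, gene) UMI sets and read tallies in one pass."""
    umis: dict[tuple[str, str], set] = {}
    read_counts: dict[tuple[str, str], int] = {}
    allowed = set(whitelist) if whitelist is not None else None
    for r in reads:
        if not r.gene:
            raise ValueError("gene identifier must be non-empty")
        if allowed is not None and r.cell_barcode not in allowed:
            continue
        key = (r.cell_barcode, r.gene)
        umis.setdefault(key, set()).add(r.umi)
        read_counts[key] = read_counts.get(key, 0) + 1
    return umis, read_counts


def _assemble(
    values: dict[tuple[str, str], int], whitelist: list[str] | None
) -> DigitalExpressionMatrix:
    genes = sorted({g for (_, g) in values})
    if whitelist is not None:
        cells = list(whitelist)
    else:
        cells = sorted({c for (c, _) in values})
    gidx = {g: i for i, g in enumerate(genes)}
    cidx = {c: i for i, c in enumerate(cells)}
    counts = np.zeros((len(genes), len(cells)), dtype=np.int64)
    for (c, g), v in values.items():
        counts[gidx[g], cidx[c]] = v
    return DigitalExpressionMatrix(genes=genes, cells=cells, counts=counts)


def count_umis(
    reads: Iterable[GeneTaggedRead],
    collapse: Literal["exact", "hamming1"] = "hamming1",
    whitelist: list[str] | None = None,
) -> DigitalExpressionMatrix:
    """Count distinct UMIs per (cell, gene).

    ``collapse="hamming1"`` merges UMIs within Hamming distance 1 by
    single linkage (sequencing-error absorption, the default);
    ``"exact"`` counts distinct UMI strings.  With a ``whitelist``, reads
    from other barcodes are dropped and the cell axis follows it.
    """
    if collapse not in ("exact", "hamming1"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    umis, _ = _collect(reads, whitelist)
    values = {}
    for key, uset in umis.items():
        if collapse == "exact":
            values[key] = len(uset)
        else:
            values[key] = _hamming1_components(sorted(uset))
    return _assemble(values, whitelist)


def count_reads(
    reads: Iterable[GeneTaggedRead], whitelist: list[str] | None = None
) -> DigitalExpressionMatrix:
    """Count reads per (cell, gene) with no UMI filtering."""
    _, read_counts = _collect(reads, whitelist)
    return _assemble(read_counts, whitelist)


def filter_cells(
    matrix: DigitalExpressionMatrix, min_genes: int
) -> DigitalExpressionMatrix:
    """Retain cells detecting at least ``min_genes`` genes (inclusive)."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    keep = matrix.genes_per_cell >= min_genes
    if not keep.any():
        warnings.warn("all cells removed by gene-count filter", stacklevel=2)
    return DigitalExpressionMatrix(
        genes=list(matrix.genes),
        cells=[c for c, k in zip(matrix.cells, keep) if k],
        counts=matrix.counts[:, keep],
    )


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # shape (n_genes, n_cells), real
    genes: list[str]
    cells: list[str]
    scale_target: float
    gene_scaled: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


def normalize(
    matrix: DigitalExpressionMatrix,
    scale_target: float | Literal["mean_total"] = 10_000,
    scale_genes: bool = False,
) -> NormalizedMatrix:
    """Depth-normalise, log-transform, and optionally z-scale genes.

    Each cell's counts are rescaled so its total equals ``scale_target``
    (10,000 or the mean of per-cell totals), incremented by 1 and
    natural-log-transformed.  With ``scale_genes`` each gene row is then
    centred to mean 0 and variance 1.
    """
    totals = matrix.cell_totals.astype(float)
    if (totals == 0).any():
        raise ValueError(
            "matrix contains zero-total cells; run filter_cells first"
        )
    target = float(np.mean(totals)) if scale_target == "mean_total" else float(scale_target)
    scaled = matrix.counts * (target / totals)[None, :]
    values = np.log1p(scaled)
    if scale_genes:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    return NormalizedMatrix(
        values=values,
        genes=list(matrix.genes),
        cells=list(matrix.cells),
        scale_target=target,
        gene_scaled=scale_genes,
    )


def mito_fraction(matrix: DigitalExpressionMatrix, prefix: str = "mt-") -> pd.Series:
    """Per-cell fraction of counts on mitochondrial genes (name prefix match)."""
    is_mito = np.array([g.startswith(prefix) for g in matrix.genes])
    totals = matrix.cell_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, matrix.counts[is_mito].sum(axis=0) / totals, 0.0)
    return pd.Series(frac, index=matrix.cells, name="mito_fraction")


def read_tagged_tsv(path) -> list[GeneTaggedRead]:
    """Read a headered TSV of gene-tagged reads (cell_barcode, umi, gene[, pool])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_barcode", "umi", "gene"):
        if col not in df.columns:
            raise ValueError(f"tagged-read table missing column {col!r}")
    pools = df["pool"] if "pool" in df.columns else [None] * len(df)
    return [
        GeneTaggedRead(c, u, g, p)
        for c, u, g, p in zip(df["cell_barcode"], df["umi"], df["gene"], pools)
    ]


def read_tagged_sam(path) -> list[GeneTaggedRead]:
    """Read gene-tagged reads from a SAM file carrying XC/XM/GE tags."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if not (rec.has_tag("XC") and rec.has_tag("XM") and rec.has_tag("GE")):
                continue
            out.append(
                GeneTaggedRead(rec.get_tag("XC"), rec.get_tag("XM"), rec.get_tag("GE"))
            )
    return out
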