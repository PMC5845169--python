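"""Classification of within-cell-type variable genes by cell-cycle association.

Cells are ranked by their DNA-stain (Hoechst) intensity and split into
equal-sized rank buckets.  For every gene two coefficients of variation are
computed: across bin-averaged expression (tracking the cell cycle) and
across single cells (tracking all variability).  After z-scaling each CV
distribution over genes, a high bin-CV z-score marks a cell-cycle-associated
variable gene, while a large excess of the cell-CV z-score over the bin-CV
z-score marks a variable gene less associated with the cell cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import DigitalExpressionMatrix

__all__ = [
    "CellMetadata",
    "hoechst_bins",
    "classify_variable_genes",
    "cv_threshold_report",
    "read_flow_table",
]

CLASS_CYCLE = "cell_cycle_associated"
CLASS_VARIABLE = "variable_less_associated"
CLASS_NONE = "not_variable"


@dataclass
class CellMetadata:
    """Per-cell flow-cytometry channels keyed by cell barcode."""

    table: pd.DataFrame  # index: cell_barcode; columns incl. hoechst

    def __post_init__(self):
        if "hoechst" not in self.table.columns:
            raise ValueError("cell metadata needs a 'hoechst' column")
        if (self.table["hoechst"] < 0).any():
            raise ValueError("hoechst intensity must be non-negative")


def read_flow_table(path) -> CellMetadata:
    """Read a headered flow-cytometry TSV (cell_barcode, hoechst[, calcein, ssc])."""
    df = pd.read_csv(path, sep="\t")
    if "cell_barcode" not in df.columns:
        raise ValueError("flow table needs a 'cell_barcode' column")
    return CellMetadata(table=df.set_index("cell_barcode"))


def hoechst_bins(metadata: CellMetadata, n_bins: int = 40) -> pd.Series:
    """Assign each cell to one of ``n_bins`` equal-sized rank buckets.

    Cells are ordered by Hoechst intensity (ties broken by stable input
    order) and bucket ``i`` receives ranks ``[floor(i*n/B), floor((i+1)*n/B))``,
    so bucket sizes differ by at most one.  Returns a Series of bin indices
    (0-based, increasing with intensity) indexed by cell barcode.
    """
    n = len(metadata.table)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of cells ({n})")
    order = np.argsort(metadata.table["hoechst"].to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    boundaries = np.array([(b * n) // n_bins for b in range(1, n_bins + 1)])
    bins = np.searchsorted(boundaries, ranks, side="right")
    return pd.Series(bins, index=metadata.table.index, name="bin")


def _cv(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean > 0, sd / mean, 0.0)


def classify_variable_genes(
    matrix: DigitalExpressionMatrix,
    bins: pd.Series,
    z_threshold: float = 2.0,
    diff_threshold: float = 2.0,
    depth_normalize: bool = True,
) -> pd.DataFrame:
    """Compute bin-CV and cell-CV z-scores per gene and classify.

    With ``depth_normalize`` (default) counts are first rescaled so every
    cell has the mean total, preventing sequencing depth from masquerading
    as cycle signal; disable for the literal raw-count reading.

    Returns a frame indexed by gene with columns ``bin_cv``, ``cell_cv``,
    ``z_bin``, ``z_cell`` and ``class``.  Genes with zero mean expression
    are excluded.
    """
    cells = [c for c in matrix.cells if c in bins.index]
    if len(cells) != len(matrix.cells):
        missing = len(matrix.cells) - len(cells)
        raise ValueError(f"{missing} matrix cells missing from bin assignment")
    bin_ids = bins.loc[matrix.cells].to_numpy()
    n_bins = int(bin_ids.max()) + 1
    if n_bins < 2:
        raise ValueError("need at least 2 bins")

    counts = matrix.counts.astype(float)
    if depth_normalize:
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("zero-total cells present; run filter_cells first")
        counts = counts * (totals.mean() / totals)[None, :]

    expressed = counts.mean(axis=1) > 0
    counts = counts[expressed]
    genes = [g for g, e in zip(matrix.genes, expressed) if e]

    bin_means = np.column_stack(
        [counts[:, bin_ids == b].mean(axis=1) for b in range(n_bins)]
    )
    bin_cv = _cv(bin_means, axis=1)
    cell_cv = _cv(counts, axis=1)

    def zscale(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_bin = zscale(bin_cv)
    z_cell = zscale(cell_cv)

    cls = np.full(len(genes), CLASS_NONE, dtype=object)
    cycle = z_bin >= z_threshold
    variable = (~cycle) & ((z_cell - z_bin) >= diff_threshold)
    cls[cycle] = CLASS_CYCLE
    cls[variable] = CLASS_VARIABLE
    return pd.DataFrame(
        {
            "bin_cv": bin_cv,
            "cell_cv": cell_cv,
            "z_bin": z_bin,
            "z_cell": z_cell,
            "class": cls,
        },
        index=genes,
    )


def cv_threshold_report(
    results: pd.DataFrame, z_values=(1, 2, 3, 4), diff_threshold: float = 2.0
) -> pd.DataFrame:
    """Gene counts per class across a sweep of z thresholds.

    Also emits the CV value each z maps to (mean + z * sd of the bin-CV
    distribution), mirroring the usual threshold-annotation convention.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["z", "cv_at_z", "n_cell_cycle", "n_variable_less", "n_not_variable"]
        ).set_index("z")
    mu, sd = results["bin_cv"].mean(), results["bin_cv"].std(ddof=0)
    rows = []
    for z in z_values:
        cycle = results["z_bin"] >= z
        variable = (~cycle) & ((results["z_cell"] - results["z_bin"]) >= diff_threshold)
        rows.append(
            {
                "z": z,
                "cv_at_z": mu + z * sd,
                "n_cell_cycle": int(cycle.sum()),
                "n_variable_less": int(variable.sum()),
                "n_not_variable": int((~cycle & ~variable).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("z")
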