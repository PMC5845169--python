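"""Quantitative benchmarks: UMI conversion efficiency and spike-in metrics.

UMI conversion efficiency measures how effectively initial fastq reads are
converted into UMI counts: per cell, ``umi_sc / (fastq_sc + fastq_non_sc)``,
where the denominator is the cell's share of all initial reads (single-cell
derived plus experimental-byproduct reads).  Spike-in capture efficiency is
the through-origin regression slope of detected UMIs against known input
molecules; ``m50`` is the input copy number detected in half of the cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counting import DigitalExpressionMatrix

__all__ = [
    "ConversionStats",
    "ERCCReference",
    "DetectionCurve",
    "umi_conversion_efficiency",
    "ercc_capture_efficiency",
    "molecules_at_half_detection",
    "molecules_per_well",
    "read_ercc_reference",
]

AVOGADRO = 6.02214076e23


@dataclass
class ConversionStats:
    """Per-cell read-to-UMI conversion ledger and its summary."""

    per_cell: pd.DataFrame  # columns: initial_reads, umi_sc, efficiency
    mean_efficiency: float
    sd_efficiency: float

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_efficiency

    @property
    def sd_percent(self) -> float:
        return 100.0 * self.sd_efficiency


def umi_conversion_efficiency(
    initial_reads: int | np.ndarray | pd.Series,
    matrix: DigitalExpressionMatrix,
) -> ConversionStats:
    """Compute per-cell UMI conversion efficiency and its mean +/- sd.

    ``initial_reads`` is either the total initial fastq read count (split
    equally across the matrix's cells) or a per-cell vector/Series of read
    tallies from demultiplexing.
    """
    n = len(matrix.cells)
    if n == 0:
        raise ValueError("matrix has no cells")
    if np.isscalar(initial_reads):
        if initial_reads <= 0:
            raise ValueError("initial read count must be positive")
        reads = np.full(n, float(initial_reads) / n)
    else:
        if isinstance(initial_reads, pd.Series):
            reads = initial_reads.reindex(matrix.cells).to_numpy(dtype=float)
            if np.isnan(reads).any():
                raise ValueError("per-cell read tallies missing for some cells")
        else:
            reads = np.asarray(initial_reads, dtype=float)
            if reads.shape != (n,):
                raise ValueError(f"expected {n} per-cell read counts, got {reads.shape}")
        if (reads <= 0).any():
            raise ValueError("initial read counts must be positive")
    umi = matrix.cell_totals.astype(float)
    eff = umi / reads
    per_cell = pd.DataFrame(
        {"initial_reads": reads, "umi_sc": umi, "efficiency": eff},
        index=matrix.cells,
    )
    return ConversionStats(
        per_cell=per_cell,
        mean_efficiency=float(eff.mean()),
        sd_efficiency=float(eff.std(ddof=1)) if n > 1 else 0.0,
    )


@dataclass(frozen=True)
class ERCCReference:
    """Known spike-in input amounts, as molecules per well."""

    table: pd.DataFrame  # index: ercc_id; column: input_molecules

    def __post_init__(self):
        if "input_molecules" not in self.table.columns:
            raise ValueError("reference needs an 'input_molecules' column")
        if (self.table["input_molecules"] <= 0).any():
            raise ValueError("input_molecules must be positive")

    def molecules(self, ercc_ids) -> np.ndarray:
        return self.table.loc[list(ercc_ids), "input_molecules"].to_numpy(dtype=float)


def molecules_per_well(
    attomoles_per_ul: float | np.ndarray,
    dilution: float = 1.0,
    volume_ul: float = 1.0,
) -> np.ndarray:
    """Convert a stock concentration to molecule copies delivered per well."""
    amol = np.asarray(attomoles_per_ul, dtype=float)
    return amol * 1e-18 * AVOGADRO * dilution * volume_ul


def read_ercc_reference(path, dilution: float = 1.0, volume_ul: float = 1.0) -> ERCCReference:
    """Read a TSV with ercc_id plus molecules_per_well or attomoles_per_ul."""
    df = pd.read_csv(path, sep="\t")
    if "ercc_id" not in df.columns:
        raise ValueError("reference TSV needs an 'ercc_id' column")
    df = df.set_index("ercc_id")
    if "molecules_per_well" in df.columns:
        mols = df["molecules_per_well"].astype(float)
    elif "attomoles_per_ul" in df.columns:
        mols = pd.Series(
            molecules_per_well(df["attomoles_per_ul"].to_numpy(), dilution, volume_ul),
            index=df.index,
        )
    else:
        raise ValueError("reference needs molecules_per_well or attomoles_per_ul")
    return ERCCReference(table=pd.DataFrame({"input_molecules": mols}))


def _ercc_rows(matrix: DigitalExpressionMatrix, reference: ERCCReference):
    ids = [g for g in matrix.genes if g.startswith("ERCC-") and g in reference.table.index]
    if not ids:
        raise ValueError("matrix contains no ERCC-* genes covered by the reference")
    rows = np.array([matrix.genes.index(g) for g in ids])
    return ids, matrix.counts[rows, :]


def ercc_capture_efficiency(
    matrix: DigitalExpressionMatrix,
    reference: ERCCReference,
    per_species: str = "mean",
) -> float:
    """Spike-in capture efficiency as a regression-through-origin slope.

    Per species, the mean detected UMI count per cell (or the summed count
    with ``per_species="sum"``) is regressed on input molecules with zero
    intercept; the slope is the fraction of input molecules recovered.
    Returned as a fraction (multiply by 100 for percent).
    """
    ids, counts = _ercc_rows(matrix, reference)
    if len(ids) < 3:
        raise ValueError(f"only {len(ids)} ERCC species present; need >= 3")
    if per_species == "mean":
        y = counts.mean(axis=1)
    elif per_species == "sum":
        y = counts.sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown per_species mode {per_species!r}")
    x = reference.molecules(ids)
    return float(np.dot(x, y) / np.dot(x, x))


@dataclass
class DetectionCurve:
    """Logistic detection curve over spike-in species.

    ``table`` has one row per species: input_molecules and the fraction of
    cells detecting it.  ``m50`` is the input copy number at which the fitted
    curve crosses 50% detection.
    """

    table: pd.DataFrame
    intercept: float
    slope: float
    m50: float

    def predict(self, molecules: np.ndarray) -> np.ndarray:
        """Fitted detection probability; monotone nondecreasing in molecules."""
        z = self.intercept + self.slope * np.log10(np.asarray(molecules, dtype=float))
        return 1.0 / (1.0 + np.exp(-z))


def molecules_at_half_detection(
    matrix: DigitalExpressionMatrix, reference: ERCCReference
) -> DetectionCurve:
    """Fit per-cell Bernoulli detections against log10 input molecules.

    Maximum-likelihood logistic regression on (detected-or-not) over every
    (species, cell) pair; the 50% point is solved in closed form from the
    coefficients.  Requires detection probabilities both below and above 0.5.
    """
    ids, counts = _ercc_rows(matrix, reference)
    mols = reference.molecules(ids)
    det_frac = (counts > 0).mean(axis=1)
    if det_frac.min() >= 0.5 or det_frac.max() <= 0.5:
        raise ValueError(
            "species detection probabilities do not bracket 0.5 "
            f"(observed range {det_frac.min():.3f}-{det_frac.max():.3f})"
        )
    n_cells = counts.shape[1]
    y = (counts > 0).astype(float).ravel()
    x = np.repeat(np.log10(mols), n_cells)
    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=0)
    b0, b1 = fit.params
    if b1 <= 0:
        raise ValueError("fitted detection curve is not increasing in input molecules")
    m50 = 10.0 ** (-b0 / b1)
    table = pd.DataFrame(
        {"input_molecules": mols, "detection_probability": det_frac}, index=ids
    ).sort_values("input_molecules")
    return DetectionCurve(table=table, intercept=float(b0), slope=float(b1), m50=float(m50))
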