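"""Ground-truthed synthetic datasets for exercising the full pipeline.

Generates negative-binomial expression with optional two-cluster
differential structure and a cell-cycle program tied to a simulated DNA
content, spike-in capture, PCR-duplicated barcoded reads with injected
barcode errors, and a matching flow-cytometry table.  Every emitted file is
a deterministic function of the configuration seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import BASES, BarcodeSet
from .demux import ReadRecord

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cells", "emit_reads", "emit_flow_table"]

_DNA_PATTERNS = {
    # P(G1), P(S), P(G2/M): embryonic populations sit mostly in G2/M,
    # somatic ones mostly in G1
    "embryonic": (0.25, 0.25, 0.50),
    "somatic": (0.60, 0.25, 0.15),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 96
    n_genes: int = 200
    barcode_set: BarcodeSet | None = None
    # gene mean grid: log-normal across genes
    gene_mean_log_mu: float = 0.5
    gene_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.2  # var = mu + dispersion * mu^2; 0 -> Poisson
    # cluster structure
    n_clusters: int = 2
    de_fraction: float = 0.236
    de_lfc_shape: float = 1.02
    de_lfc_rate: float = 0.78
    # cell-cycle program
    cycle_fraction: float = 0.0
    dna_pattern: str = "embryonic"
    # spike-ins
    ercc_molecules: tuple[tuple[str, float], ...] = ()
    ercc_capture_p: float = 0.05
    # read emission
    duplication_mean: float = 5.0
    sub_rate: float = 0.005
    ins_rate: float = 0.001
    del_rate: float = 0.001
    byproduct_fraction: float = 0.0
    umi_len: int = 8
    distinct_umis: bool = True
    pool_barcode: str = "TACGTA"
    read2_len: int = 30
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.de_fraction,
            self.cycle_fraction,
            self.ercc_capture_p,
            self.sub_rate,
            self.ins_rate,
            self.del_rate,
            self.byproduct_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.dna_pattern not in _DNA_PATTERNS:
            raise ValueError(f"unknown dna_pattern {self.dna_pattern!r}")


@dataclass
class GroundTruth:
    config: SimulationConfig
    molecules: pd.DataFrame  # genes (incl. ERCC-*) x cells, true molecule counts
    cells: pd.DataFrame  # index barcode: cluster, dna_content
    genes: pd.DataFrame  # index gene: base_mean, de_flag, lfc, cycle_flag


def _default_barcodes(n_cells: int, seed: int) -> BarcodeSet:
    from .barcodes import generate_candidates, select_balanced_subset

    cands = generate_candidates(
        length=14, min_distance=5, target_count=max(n_cells, 8), seed=seed
    )
    return select_balanced_subset(cands, k=n_cells, seed=seed, min_distance=5)


def simulate_cells(config: SimulationConfig) -> GroundTruth:
    """Draw per-cell true molecule counts and all latent per-cell/gene state."""
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes

    barcode_set = config.barcode_set
    if barcode_set is None and n_cells > 0:
        barcode_set = _default_barcodes(n_cells, config.seed)
    if barcode_set is not None and len(barcode_set) < n_cells:
        raise ValueError(
            f"barcode set has {len(barcode_set)} sequences for {n_cells} cells"
        )
    barcodes = barcode_set.sequences[:n_cells] if barcode_set is not None else []
    gene_names = [f"gene{i + 1:05d}" for i in range(n_genes)]

    base_mean = rng.lognormal(config.gene_mean_log_mu, config.gene_mean_log_sigma, n_genes)
    de_flag = rng.random(n_genes) < config.de_fraction
    lfc = np.zeros(n_genes)
    if de_flag.any():
        mags = rng.gamma(config.de_lfc_shape, 1.0 / config.de_lfc_rate, int(de_flag.sum()))
        signs = rng.choice([-1.0, 1.0], int(de_flag.sum()))
        lfc[de_flag] = mags * signs
    cycle_flag = rng.random(n_genes) < config.cycle_fraction

    cluster = rng.integers(0, config.n_clusters, n_cells)
    probs = _DNA_PATTERNS[config.dna_pattern]
    phase = rng.choice(3, size=n_cells, p=probs)
    dna = np.where(phase == 0, 1.0, np.where(phase == 2, 2.0, rng.uniform(1.0, 2.0, n_cells)))

    # per-cell per-gene expected molecules
    mu = np.tile(base_mean[:, None], (1, n_cells))
    mu[np.ix_(de_flag, cluster == 1)] *= 2.0 ** lfc[de_flag][:, None]
    # cycle genes double in mean across the DNA-content range [1, 2]
    mu[cycle_flag] *= dna[None, :]

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    molecules = rng.poisson(lam).astype(np.int64)

    frames = [pd.DataFrame(molecules, index=gene_names, columns=barcodes)]
    if config.ercc_molecules:
        ids = [eid for eid, _ in config.ercc_molecules]
        input_m = np.array([m for _, m in config.ercc_molecules])
        captured = rng.binomial(
            np.round(input_m).astype(np.int64)[:, None], config.ercc_capture_p,
            size=(len(ids), n_cells),
        )
        frames.append(pd.DataFrame(captured, index=ids, columns=barcodes))
    mol_frame = pd.concat(frames) if n_cells > 0 else pd.DataFrame(
        index=gene_names + [eid for eid, _ in config.ercc_molecules]
    )

    cells = pd.DataFrame({"cluster": cluster, "dna_content": dna}, index=barcodes)
    genes = pd.DataFrame(
        {"base_mean": base_mean, "de_flag": de_flag, "lfc": lfc, "cycle_flag": cycle_flag},
        index=gene_names,
    )
    return GroundTruth(config=config, molecules=mol_frame, cells=cells, genes=genes)


def _random_kmer(rng: np.random.Generator, k: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, k))


def _apply_edit(rng: np.random.Generator, seq: str, kind: str) -> str:
    pos = int(rng.integers(0, len(seq)))
    if kind == "sub":
        alt = BASES.replace(seq[pos], "")
        return seq[:pos] + alt[int(rng.integers(0, 3))] + seq[pos + 1 :]
    if kind == "ins":
        return seq[:pos] + BASES[int(rng.integers(0, 4))] + seq[pos:]
    return seq[:pos] + seq[pos + 1 :]  # del


def _umi_pool(rng: np.random.Generator, m: int, umi_len: int, distinct: bool) -> list[str]:
    space = 4 ** umi_len
    if distinct:
        if m > space:
            raise ValueError(f"cannot draw {m} distinct UMIs from a space of {space}")
        codes = rng.choice(space, size=m, replace=False)
    else:
        codes = rng.integers(0, space, size=m)
    out = []
    for code in codes:
        s = []
        c = int(code)
        for _ in range(umi_len):
            s.append(BASES[c & 3])
            c >>= 2
        out.append("".join(s))
    return out


def emit_reads(
    truth: GroundTruth, outdir=None
) -> tuple[list[ReadRecord], pd.DataFrame, pd.DataFrame]:
    """Expand true molecules into PCR-duplicated, error-injected reads.

    Returns ``(reads, tagged, read_truth)``:

    * ``reads`` — :class:`ReadRecord` list (Read1 = barcode + UMI + poly-T
      pad, Index1 = pool barcode, Read2 = random cDNA);
    * ``tagged`` — gene-tagged read table (cell_barcode, umi, gene, pool),
      one row per read, standing in for aligner output;
    * ``read_truth`` — per-read provenance (true cell, gene, UMI, number of
      injected barcode edits; byproduct reads have empty cell).

    If ``outdir`` is given, writes R1/R2/I1 FASTQ, ``tagged.tsv``, truth
    tables and a whitelist there.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1)
    barcode_len = len(truth.cells.index[0]) if len(truth.cells) else 14
    read1_len = barcode_len + 2 + config.umi_len
    qual = chr(config.base_quality + 33)

    reads: list[ReadRecord] = []
    tagged_rows = []
    truth_rows = []
    p_dup = 1.0 / config.duplication_mean
    genes_by_cell = truth.molecules.T  # cells x genes

    ridx = 0
    for barcode in truth.cells.index:
        profile = genes_by_cell.loc[barcode]
        for gene, m in profile.items():
            m = int(m)
            if m == 0:
                continue
            umis = _umi_pool(rng, m, config.umi_len, config.distinct_umis)
            for umi in umis:
                n_reads = int(rng.geometric(p_dup))
                for _ in range(n_reads):
                    edited = barcode
                    n_edits = 0
                    for kind, rate in (
                        ("sub", config.sub_rate),
                        ("ins", config.ins_rate),
                        ("del", config.del_rate),
                    ):
                        if rng.random() < rate:
                            edited = _apply_edit(rng, edited, kind)
                            n_edits += 1
                    r1 = (edited + umi + "T" * read1_len)[:read1_len]
                    rid = f"r{ridx:08d}"
                    ridx += 1
                    reads.append(
                        ReadRecord(
                            read_id=rid,
                            read1_seq=r1,
                            read1_qual=tuple([config.base_quality] * len(r1)),
                            index1_seq=config.pool_barcode,
                            read2_seq=_random_kmer(rng, config.read2_len),
                        )
                    )
                    tagged_rows.append((barcode, umi, gene, "pool1"))
                    truth_rows.append((rid, barcode, gene, umi, n_edits))

    n_sc = len(reads)
    if config.byproduct_fraction > 0 and n_sc > 0:
        # byproduct reads carry no valid barcode structure at all
        n_by = int(round(n_sc * config.byproduct_fraction / (1 - config.byproduct_fraction)))
        for _ in range(n_by):
            rid = f"r{ridx:08d}"
            ridx += 1
            reads.append(
                ReadRecord(
                    read_id=rid,
                    read1_seq=_random_kmer(rng, read1_len),
                    read1_qual=tuple([config.base_quality] * read1_len),
                    index1_seq=config.pool_barcode,
                    read2_seq=_random_kmer(rng, config.read2_len),
                )
            )
            truth_rows.append((rid, "", "", "", 0))

    tagged = pd.DataFrame(tagged_rows, columns=["cell_barcode", "umi", "gene", "pool"])
    read_truth = pd.DataFrame(
        truth_rows, columns=["read_id", "cell_barcode", "gene", "umi", "n_edits"]
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fastq(outdir / "R1.fastq", [(r.read_id, r.read1_seq, qual) for r in reads])
        _write_fastq(outdir / "R2.fastq", [(r.read_id, r.read2_seq, qual) for r in reads])
        _write_fastq(outdir / "I1.fastq", [(r.read_id, r.index1_seq, qual) for r in reads])
        tagged.to_csv(outdir / "tagged.tsv", sep="\t", index=False)
        read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        truth.molecules.to_csv(outdir / "true_molecules.tsv", sep="\t")
        truth.cells.to_csv(outdir / "cell_truth.tsv", sep="\t")
        truth.genes.to_csv(outdir / "gene_truth.tsv", sep="\t")
        pd.DataFrame(
            {
                "well_id": [f"well{i + 1:04d}" for i in range(len(truth.cells))],
                "barcode": truth.cells.index,
            }
        ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    return reads, tagged, read_truth


def _write_fastq(path, records) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qchar in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def emit_flow_table(
    truth: GroundTruth, noise_sd: float = 0.05, outpath=None
) -> pd.DataFrame:
    """Per-cell flow-cytometry table derived from the simulated latent state.

    Hoechst intensity is the true DNA content under multiplicative lognormal
    measurement noise; the Calcein flag follows cluster membership; SSC is
    an uninformative lognormal channel.
    """
    rng = np.random.default_rng(truth.config.seed + 2)
    n = len(truth.cells)
    noise = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else np.ones(n)
    df = pd.DataFrame(
        {
            "cell_barcode": truth.cells.index,
            "hoechst": truth.cells["dna_content"].to_numpy() * noise,
            "calcein": (truth.cells["cluster"].to_numpy() == 0).astype(int),
            "ssc": rng.lognormal(4.0, 0.3, n),
        }
    )
    if outpath is not None:
        df.to_csv(outpath, sep="\t", index=False)
    return df
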