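"""Read-structure parsing and error-correcting demultiplexing.

Read1 carries the cell barcode followed by an 8 nt UMI; Index1 carries a 6 nt
pool barcode; Read2 is cDNA.  Cell barcodes are decoded against a verified
whitelist allowing up to two edits (substitution, insertion or deletion).
Because indels shift the downstream frame, decoding works on an observation
window of ``barcode_length + max_dist`` bases and reports how many bases the
optimal alignment consumed, which relocates the UMI window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .barcodes import BarcodeSet, _check_dna, _encode

__all__ = [
    "ReadRecord",
    "TaggedRead",
    "DemuxStats",
    "correct_barcode",
    "BarcodeCorrector",
    "tag_reads",
    "split_pools",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    read1_seq: str
    read1_qual: tuple[int, ...] | None = None
    index1_seq: str | None = None
    read2_seq: str | None = None

    def __post_init__(self):
        if self.read1_qual is not None and len(self.read1_qual) != len(self.read1_seq):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.read1_qual)} "
                f"!= sequence length {len(self.read1_seq)}"
            )


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    cell_barcode: str | None
    raw_barcode: str
    correction_distance: int | None
    umi: str | None
    pool: str | None
    status: str  # assigned | uncorrectable | low_quality


@dataclass
class DemuxStats:
    total: int = 0
    assigned: int = 0
    uncorrectable: int = 0
    low_quality: int = 0
    by_distance: dict[int, int] = field(default_factory=dict)

    def record(self, tagged: TaggedRead) -> None:
        self.total += 1
        if tagged.status == "assigned":
            self.assigned += 1
            d = tagged.correction_distance
            self.by_distance[d] = self.by_distance.get(d, 0) + 1
        elif tagged.status == "low_quality":
            self.low_quality += 1
        else:
            self.uncorrectable += 1


def _prefix_decode(window: str, pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each barcode row, the minimum edit distance to any prefix of ``window``.

    Rows of the DP index window positions i, columns index barcode positions.
    ``D[i, L]`` is the Levenshtein distance between ``window[:i]`` and the
    whole barcode; minimising over i gives the decode distance, and the
    minimising i is the number of window bases the barcode consumed.

    Returns (distances, consumed) arrays over the pool; ties in consumed
    length are broken toward the nominal barcode length, then downward.
    """
    q = _encode(window)
    n = len(q)
    N, L = pool.shape
    prev = np.broadcast_to(np.arange(L + 1, dtype=np.int32), (N, L + 1)).copy()
    last_col = np.empty((n + 1, N), dtype=np.int32)
    last_col[0] = L
    cur = np.empty_like(prev)
    for i in range(1, n + 1):
        neq = (pool != q[i - 1]).astype(np.int32)
        cur[:, 0] = i
        for j in range(1, L + 1):
            np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1, out=cur[:, j])
            np.minimum(cur[:, j], prev[:, j - 1] + neq[:, j - 1], out=cur[:, j])
        last_col[i] = cur[:, L]
        prev, cur = cur, prev
    dist = last_col.min(axis=0)
    # tie-break: prefer consumed length nearest L, then the smaller value
    order = np.argsort(np.abs(np.arange(n + 1) - L), kind="stable")
    ranked = last_col[order]
    consumed = order[np.argmin(ranked, axis=0)]
    return dist, consumed.astype(np.int64)


class BarcodeCorrector:
    """Decoder for a verified barcode set, with a per-window memo cache."""

    def __init__(self, barcode_set: BarcodeSet, max_dist: int = 2):
        if barcode_set.min_distance < 2 * max_dist + 1:
            raise ValueError(
                f"barcode set min_distance={barcode_set.min_distance} cannot "
                f"guarantee unambiguous correction of {max_dist} errors "
                f"(needs >= {2 * max_dist + 1})"
            )
        self.set = barcode_set
        self.max_dist = max_dist
        self.window_len = barcode_set.length + max_dist
        self._pool = barcode_set.encoded()
        self._exact = {s: i for i, s in enumerate(barcode_set.sequences)}
        self._cache: dict[str, tuple[str | None, int | None, int | None]] = {}

    def correct(self, observed: str) -> tuple[str | None, int | None, int | None]:
        """Decode an observation window; see :func:`correct_barcode`."""
        _check_dna(observed, "observed window")
        hit = self._cache.get(observed)
        if hit is not None:
            return hit
        L = self.set.length
        if observed[:L] in self._exact:
            result = (observed[:L], 0, L)
        elif len(observed) < L:
            # too short to contain even a maximally deleted barcode
            result = (None, None, None) if len(observed) < L - self.max_dist \
                else self._dp_decode(observed)
        else:
            result = self._dp_decode(observed[: self.window_len])
        if len(self._cache) < 1_000_000:
            self._cache[observed] = result
        return result

    def _dp_decode(self, window: str) -> tuple[str | None, int | None, int | None]:
        dist, consumed = _prefix_decode(window, self._pool)
        k = int(np.argmin(dist))
        d = int(dist[k])
        if d > self.max_dist:
            return (None, None, None)
        # min_distance >= 2*max_dist+1 makes ties impossible; guard anyway
        ties = int((dist == d).sum())
        assert ties == 1, f"ambiguous decode at distance {d} ({ties} candidates)"
        return (self.set.sequences[k], d, int(consumed[k]))


def correct_barcode(
    observed: str, barcode_set: BarcodeSet, max_dist: int = 2
) -> tuple[str | None, int | None, int | None]:
    """Decode one observation window against a barcode set.

    Returns ``(barcode, distance, consumed_length)`` where ``consumed_length``
    is the number of observed bases matched to the barcode by the optimal
    alignment (barcode length plus net indels), or ``(None, None, None)`` if
    no barcode lies within ``max_dist`` edits.
    """
    return BarcodeCorrector(barcode_set, max_dist).correct(observed)


def tag_reads(
    reads: Iterable[ReadRecord],
    barcode_set: BarcodeSet,
    umi_len: int = 8,
    quality_threshold: int | None = 10,
    max_dist: int = 2,
    stats: DemuxStats | None = None,
) -> Iterator[TaggedRead]:
    """Assign each read a corrected cell barcode and UMI.

    The UMI is taken from Read1 positions ``[consumed, consumed + umi_len)``
    so that net indels in the barcode shift it correctly; reads left too
    short by that shift are rejected rather than padded.  Reads whose barcode
    or UMI bases fall below ``quality_threshold`` (Phred) are flagged
    ``low_quality``.  Pass a :class:`DemuxStats` to collect tallies.
    """
    corrector = BarcodeCorrector(barcode_set, max_dist)
    wlen = corrector.window_len
    for read in reads:
        raw = read.read1_seq[: barcode_set.length]
        if len(read.read1_seq) < barcode_set.length - max_dist + umi_len:
            tagged = TaggedRead(read.read_id, None, raw, None, None, None, "uncorrectable")
        else:
            barcode, dist, consumed = corrector.correct(read.read1_seq[:wlen])
            if barcode is None:
                tagged = TaggedRead(read.read_id, None, raw, None, None, None, "uncorrectable")
            elif len(read.read1_seq) < consumed + umi_len:
                tagged = TaggedRead(read.read_id, None, raw, None, None, None, "uncorrectable")
            else:
                umi = read.read1_seq[consumed : consumed + umi_len]
                status = "assigned"
                if quality_threshold is not None and read.read1_qual is not None:
                    quals = read.read1_qual[: consumed + umi_len]
                    if quals and min(quals) < quality_threshold:
                        status = "low_quality"
                if status == "assigned":
                    tagged = TaggedRead(
                        read.read_id, barcode, raw, dist, umi, read.index1_seq, "assigned"
                    )
                else:
                    tagged = TaggedRead(read.read_id, None, raw, None, None, None, "low_quality")
        if stats is not None:
            stats.record(tagged)
        yield tagged


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("pool barcodes must share one length")
    return sum(x != y for x, y in zip(a, b))


def split_pools(
    reads: Iterable[ReadRecord], pool_barcodes: dict[str, str] | Sequence[tuple[str, str]]
) -> dict[str, list[ReadRecord]]:
    """Route reads by Index1 with at most one mismatch.

    ``pool_barcodes`` maps pool id -> 6 nt barcode; pairwise Hamming distance
    must be >= 3 so a single mismatch resolves uniquely.  Unmatched or
    missing-index reads land in the ``"undetermined"`` stream.
    """
    table = dict(pool_barcodes)
    ids = list(table)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = _hamming(table[ids[i]], table[ids[j]])
            if d < 3:
                raise ValueError(
                    f"pool barcodes {ids[i]} and {ids[j]} at Hamming distance {d} < 3"
                )
    out: dict[str, list[ReadRecord]] = {pid: [] for pid in ids}
    out["undetermined"] = []
    for read in reads:
        dest = "undetermined"
        if read.index1_seq is not None:
            for pid in ids:
                if len(read.index1_seq) == len(table[pid]) and _hamming(
                    read.index1_seq, table[pid]
                ) <= 1:
                    dest = pid
                    break
        out[dest].append(read)
    return out
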