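"""Design and verification of error-correcting DNA cell barcodes.

Barcodes sit at the start of a longer sequencing read, so an insertion or
deletion inside the barcode shifts every downstream base.  The distance used
here therefore allows the *end* of either word to be truncated for free: it
is the minimum over the last row and last column of the unit-cost Levenshtein
dynamic-programming matrix.  A code with minimum pairwise distance ``2e + 1``
under this metric supports unique correction of up to ``e`` edits
(substitution, insertion or deletion) during demultiplexing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeSet",
    "CompositionFilters",
    "VerifyReport",
    "seqlev_distance",
    "seqlev_distance_batch",
    "generate_candidates",
    "select_balanced_subset",
    "verify_set",
    "composition_variance",
    "read_whitelist",
    "write_whitelist",
    "CapacityError",
]

_DNA_RE = re.compile(r"^[ACGT]+$")

BASES = "ACGT"


class CapacityError(RuntimeError):
    """Raised when the attempt budget runs out before reaching the target count.

    Carries the sequences accepted so far in :attr:`achieved`.
    """

    def __init__(self, message: str, achieved: list[str]):
        super().__init__(message)
        self.achieved = achieved


def _check_dna(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    m = re.search(r"[^ACGT]", seq)
    if m:
        raise ValueError(
            f"{name} contains non-ACGT character {seq[m.start()]!r} at position {m.start()}"
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _encode_many(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.vstack([_encode(s) for s in seqs])


def seqlev_distance(a: str, b: str) -> int:
    """Edit distance between two barcodes embedded at the start of longer reads.

    Builds the full (len(a)+1) x (len(b)+1) unit-cost Levenshtein matrix and
    returns the minimum over its last row and last column, so that trailing
    bases of either word may be dropped at no cost (they would be supplied by
    the downstream read sequence).

    Raises ``ValueError`` on empty input or non-ACGT characters, naming the
    offending position.
    """
    _check_dna(a, "first sequence")
    _check_dna(b, "second sequence")
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    last_col_min = n  # D[0][n]
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        last_col_min = min(last_col_min, cur[n])
        prev = cur
    return min(last_col_min, min(prev))


def seqlev_distance_batch(query: str, pool: np.ndarray) -> np.ndarray:
    """Distances from ``query`` to every row of an encoded barcode array.

    ``pool`` is a (N, L) uint8 array (ASCII codes).  Vectorised over N; used
    for closure building and all-pairs verification where a Python-level pair
    loop would be too slow.
    """
    if pool.size == 0:
        return np.empty(0, dtype=np.int32)
    q = _encode(query)
    m = len(q)
    n = pool.shape[1]
    N = pool.shape[0]
    prev = np.broadcast_to(np.arange(n + 1, dtype=np.int32), (N, n + 1)).copy()
    col_min = np.full(N, n, dtype=np.int32)
    cur = np.empty_like(prev)
    for i in range(1, m + 1):
        neq = (pool != q[i - 1]).astype(np.int32)
        cur[:, 0] = i
        for j in range(1, n + 1):
            np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1, out=cur[:, j])
            np.minimum(cur[:, j], prev[:, j - 1] + neq[:, j - 1], out=cur[:, j])
        np.minimum(col_min, cur[:, n], out=col_min)
        prev, cur = cur, prev
    return np.minimum(col_min, prev.min(axis=1))


@dataclass(frozen=True)
class CompositionFilters:
    """Per-sequence composition constraints applied to candidate barcodes.

    Both filters can be disabled; they are design conventions, not part of
    the distance guarantee.
    """

    max_homopolymer: int | None = 3  # longest allowed run; None disables
    gc_min: float | None = 0.3
    gc_max: float | None = 0.7

    def accept(self, seq: str) -> bool:
        if self.max_homopolymer is not None:
            if re.search(r"(.)\1{%d,}" % self.max_homopolymer, seq):
                return False
        if self.gc_min is not None or self.gc_max is not None:
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            if self.gc_min is not None and gc < self.gc_min:
                return False
            if self.gc_max is not None and gc > self.gc_max:
                return False
        return True

    @classmethod
    def none(cls) -> "CompositionFilters":
        return cls(max_homopolymer=None, gc_min=None, gc_max=None)


@dataclass
class BarcodeSet:
    """A fixed-length DNA code with a guaranteed minimum pairwise distance."""

    sequences: list[str]
    length: int
    min_distance: int
    composition_variance: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        for s in self.sequences:
            _check_dna(s, "barcode")
            if len(s) != self.length:
                raise ValueError(
                    f"barcode {s!r} has length {len(s)}, expected {self.length}"
                )
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("barcode set contains duplicate sequences")
        if np.isnan(self.composition_variance):
            self.composition_variance = composition_variance(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        return _encode_many(self.sequences)


def composition_variance(seqs: Sequence[str]) -> float:
    """Variance over {A,C,G,T} of base frequencies pooled across all positions."""
    if not seqs:
        return 0.0
    counts = np.zeros(4)
    for i, b in enumerate(BASES):
        counts[i] = sum(s.count(b) for s in seqs)
    freqs = counts / counts.sum()
    return float(np.var(freqs))


def _base_count_vectors(seqs: Sequence[str]) -> np.ndarray:
    out = np.zeros((len(seqs), 4))
    for k, s in enumerate(seqs):
        for i, b in enumerate(BASES):
            out[k, i] = s.count(b)
    return out


def generate_candidates(
    length: int,
    min_distance: int,
    target_count: int,
    filters: CompositionFilters | None = None,
    seed: int = 0,
    attempt_budget: int = 1_000_000,
) -> list[str]:
    """Grow a random greedy closure of barcodes with pairwise distance >= ``min_distance``.

    Random ``length``-mers are drawn with a seeded generator, screened by the
    composition ``filters``, and accepted iff their distance to every
    already-accepted sequence is at least ``min_distance``.  Because the
    boundary-minimum distance is bounded above by the Hamming distance, a
    cheap Hamming pre-screen rejects most conflicting draws before the full
    DP is run.

    Returns at least ``target_count`` sequences, or raises
    :class:`CapacityError` (carrying the achieved closure) once
    ``attempt_budget`` draws are exhausted.  Output order is acceptance order;
    rerunning with the same seed reproduces it exactly.
    """
    if length < min_distance:
        raise ValueError("length must be >= min_distance")
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if filters is None:
        filters = CompositionFilters()

    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    seen: set[str] = set()
    pool = np.empty((0, length), dtype=np.uint8)
    # draw in blocks to amortise RNG overhead
    block = 512
    attempts = 0
    while attempts < attempt_budget and len(accepted) < target_count:
        draws = rng.integers(0, 4, size=(block, length))
        for row in draws:
            attempts += 1
            if attempts > attempt_budget:
                break
            seq = "".join(BASES[int(x)] for x in row)
            if seq in seen:
                continue
            seen.add(seq)
            if not filters.accept(seq):
                continue
            if len(accepted) > 0:
                q = _encode(seq)
                hamming = (pool != q).sum(axis=1)
                if int(hamming.min()) < min_distance:
                    continue
                if int(seqlev_distance_batch(seq, pool).min()) < min_distance:
                    continue
            accepted.append(seq)
            pool = np.vstack([pool, _encode(seq)])
            if len(accepted) >= target_count:
                break
    if len(accepted) < target_count:
        raise CapacityError(
            f"attempt budget {attempt_budget} exhausted: reached "
            f"{len(accepted)} of {target_count} requested sequences",
            accepted,
        )
    return accepted


def _greedy_exchange(
    vecs: np.ndarray, k: int, rng: np.random.Generator, max_swaps: int
) -> tuple[np.ndarray, float]:
    n = vecs.shape[0]
    idx = rng.choice(n, size=k, replace=False)
    chosen = np.zeros(n, dtype=bool)
    chosen[idx] = True
    total = vecs[chosen].sum(axis=0)
    best_var = float(np.var(total / total.sum()))
    for _ in range(max_swaps):
        if chosen.all():
            break
        in_idx = np.nonzero(chosen)[0]
        out_idx = np.nonzero(~chosen)[0]
        # totals for every (remove, add) pair: (n_in, n_out, 4)
        trial = total[None, None, :] - vecs[in_idx][:, None, :] + vecs[out_idx][None, :, :]
        freqs = trial / trial.sum(axis=2, keepdims=True)
        variances = freqs.var(axis=2)
        pos = np.unravel_index(np.argmin(variances), variances.shape)
        if variances[pos] >= best_var - 1e-15:
            break
        chosen[in_idx[pos[0]]] = False
        chosen[out_idx[pos[1]]] = True
        total = total - vecs[in_idx[pos[0]]] + vecs[out_idx[pos[1]]]
        best_var = float(variances[pos])
    return chosen, best_var


def select_balanced_subset(
    candidates: Sequence[str],
    k: int,
    seed: int = 0,
    min_distance: int | None = None,
    max_swaps: int = 2000,
    restarts: int = 8,
) -> BarcodeSet:
    """Choose ``k`` candidates whose pooled base composition is most uniform.

    Runs ``restarts`` greedy local searches, each starting from a seeded
    random subset and repeatedly applying the single in/out swap that most
    decreases :func:`composition_variance` until no swap improves it; the
    best restart wins.  Subsetting cannot violate the pairwise-distance
    invariant, so the result inherits ``min_distance`` from the candidates.
    """
    candidates = list(candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds number of candidates ({len(candidates)})")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidates contain duplicates")
    length = len(candidates[0])
    if min_distance is None:
        min_distance = 0

    vecs = _base_count_vectors(candidates)
    rng = np.random.default_rng(seed)
    best_chosen, best_var = None, np.inf
    for _ in range(max(restarts, 1)):
        chosen, var = _greedy_exchange(vecs, k, rng, max_swaps)
        if var < best_var - 1e-15:
            best_chosen, best_var = chosen, var
        if best_var <= 1e-15:
            break
    subset = sorted(np.array(candidates)[best_chosen].tolist())
    total = vecs[best_chosen].sum(axis=0)
    return BarcodeSet(
        sequences=subset,
        length=length,
        min_distance=min_distance,
        composition_variance=float(np.var(total / total.sum())),
    )


@dataclass(frozen=True)
class VerifyReport:
    min_observed_distance: int
    required_distance: int
    offending_pair: tuple[str, str] | None
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.passed:
            return (
                f"PASS: minimum pairwise distance {self.min_observed_distance} "
                f">= {self.required_distance}"
            )
        return (
            f"FAIL: pair {self.offending_pair} at distance "
            f"{self.min_observed_distance} < {self.required_distance}"
        )


def verify_set(barcode_set: BarcodeSet) -> VerifyReport:
    """Exhaustively check every pairwise distance against ``min_distance``."""
    seqs = barcode_set.sequences
    required = barcode_set.min_distance
    best = barcode_set.length + 1
    worst_pair: tuple[str, str] | None = None
    enc = barcode_set.encoded()
    for i in range(len(seqs) - 1):
        d = seqlev_distance_batch(seqs[i], enc[i + 1 :])
        j = int(np.argmin(d))
        if int(d[j]) < best:
            best = int(d[j])
            worst_pair = (seqs[i], seqs[i + 1 + j])
    if len(seqs) < 2:
        return VerifyReport(barcode_set.length, required, None, True)
    passed = best >= required
    return VerifyReport(best, required, None if passed else worst_pair, passed)


def write_whitelist(barcode_set: BarcodeSet, path) -> None:
    """Write a headered TSV whitelist (well_id, barcode), one row per well."""
    df = pd.DataFrame(
        {
            "well_id": [f"well{i + 1:04d}" for i in range(len(barcode_set))],
            "barcode": barcode_set.sequences,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_whitelist(path, min_distance: int = 5) -> BarcodeSet:
    """Read a whitelist TSV; extra columns are tolerated and ignored."""
    df = pd.read_csv(path, sep="\t")
    if "barcode" not in df.columns:
        raise ValueError("whitelist must have a 'barcode' column")
    seqs = [str(s) for s in df["barcode"]]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
    return BarcodeSet(sequences=seqs, length=lengths.pop(), min_distance=min_distance)
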