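import numpy as np
import pytest

import plateseq as ps


def plain_levenshtein(a: str, b: str) -> int:
    """Independent full-matrix unit-cost edit distance (test oracle)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def oracle_seqlev(a: str, b: str) -> int:
    """Boundary-minimum distance by enumerating truncations of either word."""
    best = min(plain_levenshtein(a, b[:j]) for j in range(len(b) + 1))
    return min(best, min(plain_levenshtein(a[:i], b) for i in range(len(a) + 1)))


def oracle_prefix_distance(barcode: str, window: str) -> int:
    """Min edit distance from the barcode to any prefix of the window."""
    return min(plain_levenshtein(barcode, window[:j]) for j in range(len(window) + 1))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def edit_variants(seq: str) -> set[str]:
    """All strings reachable from seq by exactly one substitution/insertion/deletion."""
    out = set()
    for i in range(len(seq)):
        for b in "ACGT":
            if b != seq[i]:
                out.add(seq[:i] + b + seq[i + 1 :])
        out.add(seq[:i] + seq[i + 1 :])
    for i in range(len(seq) + 1):
        for b in "ACGT":
            out.add(seq[:i] + b + seq[i:])
    out.discard(seq)
    return out


@pytest.fixture(scope="session")
def small_set() -> ps.BarcodeSet:
    """32 barcodes of length 14 at minimum distance 5 (fast decode fixture)."""
    cands = ps.generate_candidates(length=14, min_distance=5, target_count=40, seed=7)
    return ps.select_balanced_subset(cands, k=32, seed=7, min_distance=5)


@pytest.fixture(scope="session")
def design_384() -> ps.BarcodeSet:
    """A full 384-well design, shared by the acceptance-scale tests."""
    cands = ps.generate_candidates(length=14, min_distance=5, target_count=480, seed=1)
    return ps.select_balanced_subset(cands, k=384, seed=1, min_distance=5)
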