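"""Low-level sequence helpers shared by the simulator, annotator and miner."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_substitutions(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n distinct random substitutions (never silent: new base != old base)."""
    if n_subs <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    shift = rng.integers(1, 4, size=len(pos))
    codes = _CODE[arr.view(np.uint8)[pos]]
    arr[pos] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode()


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0 C=1 G=2 T=3; anything else 255)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit packed k-mer values at every position (k <= 31).

    Positions whose window contains a non-ACGT code get the sentinel 2^63
    (no valid k-mer can reach it for k <= 31).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        bad |= window == 255
        h = (h << np.uint64(2)) | window.astype(np.uint64)
    h[bad] = np.uint64(1) << np.uint64(63)
    return h


class KmerIndex:
    """Sorted k-mer index over one sequence for exact anchor lookup."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.hashes = kmer_hashes(encode(seq), k)
        self.order = np.argsort(self.hashes, kind="stable").astype(np.int64)
        self.sorted = self.hashes[self.order]

    def lookup(self, kmer_hash: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted, kmer_hash, side="left")
        hi = np.searchsorted(self.sorted, kmer_hash, side="right")
        return self.order[lo:hi]

    def lookup_many(self, kmer_hashes_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup; returns (lo, hi) ranges into self.order."""
        lo = np.searchsorted(self.sorted, kmer_hashes_arr, side="left")
        hi = np.searchsorted(self.sorted, kmer_hashes_arr, side="right")
        return lo, hi


def lce_forward(a: str, ai: int, b: str, bi: int, limit: int | None = None) -> int:
    """Length of the exact common extension of a[ai:] vs b[bi:]."""
    n = min(len(a) - ai, len(b) - bi)
    if limit is not None:
        n = min(n, limit)
    i = 0
    while i < n and a[ai + i] == b[bi + i]:
        i += 1
    return i


def lce_backward(a: str, ai: int, b: str, bi: int, limit: int | None = None) -> int:
    """Length of the exact common extension of a[:ai] vs b[:bi], read right-to-left."""
    n = min(ai, bi)
    if limit is not None:
        n = min(n, limit)
    i = 0
    while i < n and a[ai - 1 - i] == b[bi - 1 - i]:
        i += 1
    return i


def xdrop_forward(a: str, ai: int, b: str, bi: int, xdrop: int = 9,
                  match: int = 1, mismatch: int = 3) -> int:
    """Greedy gapless extension of a[ai:] vs b[bi:] with an x-drop stop.

    Returns the extension length at the score maximum, i.e. the last position
    worth keeping in a local alignment sense.
    """
    n = min(len(a) - ai, len(b) - bi)
    score = best = 0
    best_i = 0
    i = 0
    while i < n:
        score += match if a[ai + i] == b[bi + i] else -mismatch
        i += 1
        if score > best:
            best, best_i = score, i
        elif best - score > xdrop:
            break
    return best_i


def xdrop_backward(a: str, ai: int, b: str, bi: int, xdrop: int = 9,
                   match: int = 1, mismatch: int = 3) -> int:
    n = min(ai, bi)
    score = best = 0
    best_i = 0
    i = 0
    while i < n:
        score += match if a[ai - 1 - i] == b[bi - 1 - i] else -mismatch
        i += 1
        if score > best:
            best, best_i = score, i
        elif best - score > xdrop:
            break
    return best_i


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def max_n_run(seq: str) -> int:
    run = best = 0
    for c in seq:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


def low_complexity(seq: str, threshold: float = 0.85) -> bool:
    """Dust-style stand-in: flag sequences dominated by a single base."""
    if not seq:
        return True
    counts = np.bincount(encode(seq), minlength=5)
    return counts[:4].max() / len(seq) >= threshold
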