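"""Exhaustive brute-force oracles, written independently of the package internals.

These deliberately enumerate every candidate and pick the winner with explicit
sort keys, so they stay slow, simple and obviously correct.
"""

from __future__ import annotations


def brute_tsd(left_window: str, right_window: str, max_tsd: int = 30,
              max_mismatch_frac: float = 0.10, min_tsd: int = 5,
              max_left_offset: int = 0, max_right_offset: int = 0):
    """All (length, left offset, right offset) candidates, best by the tie rules:
    longest, then fewest mismatches, then smallest offsets (leftmost)."""
    nl, nr = len(left_window), len(right_window)
    candidates = []
    for length in range(min_tsd, min(max_tsd, nl, nr) + 1):
        for loff in range(max_left_offset + 1):
            if loff + length > nl:
                continue
            s = left_window[nl - loff - length: nl - loff]
            for roff in range(max_right_offset + 1):
                if roff + length > nr:
                    continue
                t = right_window[roff: roff + length]
                if s[0] != t[0] or s[-1] != t[-1]:
                    continue
                mm = sum(a != b for a, b in zip(s, t))
                if mm <= int(max_mismatch_frac * length):
                    candidates.append((-length, mm, loff + roff, roff, s))
    if not candidates:
        return None
    best = sorted(candidates)[0]
    return best[4], best[1]


def brute_microhomology(donor_junction: str, ctx5: str, ctx3: str,
                        max_mh: int = 30) -> int:
    """All lengths 0..max_mh; keep those satisfying the definition; return the max."""
    mid = len(donor_junction) // 2
    valid = [0]
    for m in range(1, min(max_mh, len(ctx5), len(ctx3), mid) + 1):
        s = ctx5[-m:]
        if ctx3[:m] != s:
            continue
        window = donor_junction[mid - m: mid + m]
        occurrences = [i for i in range(len(window) - m + 1) if window[i:i + m] == s]
        if len(occurrences) == 1:
            valid.append(m)
    return max(valid)


def brute_infix_divergence(query: str, target: str) -> float:
    """Exhaustive DP infix alignment (query inside target, free target end gaps);
    divergence = edits / len(query) * 100."""
    nq, nt = len(query), len(target)
    prev = [0] * (nt + 1)  # free leading target gaps
    for i in range(1, nq + 1):
        cur = [i] + [0] * nt
        for j in range(1, nt + 1):
            sub = prev[j - 1] + (query[i - 1] != target[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev) / max(1, nq) * 100.0
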