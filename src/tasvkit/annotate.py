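"""Miniature homology-based repeat annotator.

Strategy: exact k-mer anchors between genome and consensus (both strands) are
grouped by alignment diagonal, chained into candidate copies, extended with a
greedy x-drop, and scored with a banded edit-distance alignment (edlib). This is
deliberately a desk-scale stand-in for a full repeat masker: it assumes repeat
copies diverge mostly by substitutions and modest indels, which is how the
companion simulator plants them; user genomes with heavily rearranged copies
will yield fragmented hits.

Divergence is reported as (mismatches + indels) / alignment length, in percent.
Reverse-strand hits report consensus coordinates on the forward consensus.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping

import edlib
import numpy as np
import pandas as pd

from .genome import RepeatAnnotation
from .io import BedRecord
from .library import ConsensusLibrary, TEConsensus
from .sequtil import (KmerIndex, encode, kmer_hashes, low_complexity, revcomp,
                      xdrop_backward, xdrop_forward)


@dataclass
class AnnotationHit(RepeatAnnotation):
    score: int = 0


_KMER_COUNT_CAP = 5000  # ignore pathologically repetitive anchor k-mers
_MIN_ANCHORS = 2


def _clusters_from_anchors(gpos: np.ndarray, cpos: np.ndarray, band: int,
                           max_gap: int):
    """Split (genome, consensus) anchor pairs into per-copy chains.

    Anchors are grouped by alignment diagonal (tolerance ``band``) and then by
    genome-position gaps; substitution-diverged copies keep a constant diagonal,
    so this recovers one chain per planted copy.
    """
    diag = gpos.astype(np.int64) - cpos.astype(np.int64)
    order = np.lexsort((gpos, diag))
    diag, gpos, cpos = diag[order], gpos[order], cpos[order]
    breaks = np.flatnonzero(np.diff(diag) > band) + 1
    for group in np.split(np.arange(len(diag)), breaks):
        g, c = gpos[group], cpos[group]
        sub = np.argsort(g)
        g, c = g[sub], c[sub]
        gap_breaks = np.flatnonzero(np.diff(g) > max_gap) + 1
        for piece in np.split(np.arange(len(g)), gap_breaks):
            if len(piece) >= _MIN_ANCHORS:
                yield g[piece], c[piece]


def _align_divergence(seg: str, cons_seg: str) -> tuple[float, int]:
    """(% divergence, score) from a global edit-distance alignment."""
    res = edlib.align(seg, cons_seg, mode="NW", task="distance")
    edits = res["editDistance"]
    aln_len = max(len(seg), len(cons_seg))
    div = 100.0 * edits / aln_len if aln_len else 0.0
    return div, len(seg) - 3 * edits


def scan(contigs: Mapping[str, str], library: ConsensusLibrary, min_len: int = 50,
         max_divergence: float = 25.0, k: int = 13, band: int = 16,
         max_gap: int = 350) -> list[AnnotationHit]:
    """Locate TE copies in ``contigs`` and assign subfamily + consensus interval.

    Overlapping hits (the same copy matched by several related consensi) are
    resolved to the higher score; ties go to earlier library order so results
    are deterministic.
    """
    hits: list[AnnotationHit] = []
    for contig_name, seq in contigs.items():
        index = KmerIndex(seq, k)
        contig_hits: list[AnnotationHit] = []
        for lib_order, entry in enumerate(library):
            for strand in "+-":
                oriented = entry.sequence if strand == "+" else revcomp(entry.sequence)
                ch = kmer_hashes(encode(oriented), k)
                lo, hi = index.lookup_many(ch)
                counts = hi - lo
                valid = np.flatnonzero((counts > 0) & (counts <= _KMER_COUNT_CAP))
                if len(valid) == 0:
                    continue
                cpos = np.repeat(valid, counts[valid])
                gpos = np.concatenate([index.order[lo[v]:hi[v]] for v in valid])
                for g, c in _clusters_from_anchors(gpos, cpos, band, max_gap):
                    g0, g1 = int(g.min()), int(g.max()) + k
                    c0, c1 = int(c.min()), int(c.max()) + k
                    # gentle penalties: at 10-20% divergence the copy ends carry
                    # clustered mismatches that a harsher x-drop would truncate
                    ext = min(xdrop_backward(seq, g0, oriented, c0,
                                             xdrop=12, mismatch=2), c0, g0)
                    g0, c0 = g0 - ext, c0 - ext
                    ext = xdrop_forward(seq, g1, oriented, c1, xdrop=12, mismatch=2)
                    g1, c1 = g1 + ext, c1 + ext
                    if g1 - g0 < min_len:
                        continue
                    segment = seq[g0:g1]
                    if low_complexity(segment):
                        continue
                    div, score = _align_divergence(segment, oriented[c0:c1])
                    if div > max_divergence:
                        continue
                    if strand == "-":
                        L = len(entry.sequence)
                        c0, c1 = L - c1, L - c0
                    contig_hits.append(AnnotationHit(
                        contig_name, g0, g1, strand, entry.name, c0, c1,
                        round(div, 2), score=score))
        hits.extend(_resolve_overlaps(contig_hits, library))
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.subfamily))
    return hits


def _resolve_overlaps(contig_hits: list[AnnotationHit],
                      library: ConsensusLibrary,
                      max_overlap_frac: float = 0.25) -> list[AnnotationHit]:
    lib_rank = {name: i for i, name in enumerate(library.names)}
    ordered = sorted(
        contig_hits,
        key=lambda h: (-h.score, lib_rank[h.subfamily], h.cons_start, h.start))
    kept: list[AnnotationHit] = []
    starts: list[int] = []
    for hit in ordered:
        i = bisect.bisect_left(starts, hit.start - 10_000)
        ok = True
        for other in kept[i:]:
            if other.start >= hit.end:
                # kept is sorted by start; nothing further right can overlap.
                # Long hits starting earlier are covered by the 10 kb lookback.
                break
            overlap = min(hit.end, other.end) - max(hit.start, other.start)
            if overlap > max_overlap_frac * len(hit):
                ok = False
                break
        if ok:
            j = bisect.bisect_left(starts, hit.start)
            kept.insert(j, hit)
            starts.insert(j, hit.start)
    return kept


def assign_subfamily(hit_seq: str, candidates: list[TEConsensus]) -> tuple[str, float]:
    """Best-matching consensus for a repeat copy.

    Returns the candidate minimizing divergence under an infix alignment of the
    copy into the consensus (free end-gaps on the consensus, so truncations are
    not penalized); ties break by candidate order.
    """
    if not candidates:
        raise ValueError("assign_subfamily requires at least one candidate")
    best: tuple[float, int, str] | None = None
    for order, cand in enumerate(candidates):
        res = edlib.align(hit_seq, cand.sequence, mode="HW", task="distance")
        div = 100.0 * res["editDistance"] / max(1, len(hit_seq))
        key = (div, order, cand.name)
        if best is None or key < best:
            best = key
    return best[2], round(best[0], 4)


def hits_to_table(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "contig": h.contig, "start": h.start, "end": h.end, "strand": h.strand,
            "subfamily": h.subfamily, "cons_start": h.cons_start,
            "cons_end": h.cons_end, "divergence": h.divergence, "score": h.score,
        } for h in hits],
        columns=["contig", "start", "end", "strand", "subfamily",
                 "cons_start", "cons_end", "divergence", "score"])


def table_to_hits(table: pd.DataFrame) -> list[AnnotationHit]:
    return [AnnotationHit(str(r.contig), int(r.start), int(r.end), str(r.strand),
                          str(r.subfamily), int(r.cons_start), int(r.cons_end),
                          float(r.divergence), score=int(r.score))
            for r in table.itertuples()]


def hits_to_bed(hits: list[AnnotationHit]) -> list[BedRecord]:
    return [BedRecord(h.contig, h.start, h.end, h.subfamily,
                      str(int(round(h.divergence * 10))), h.strand) for h in hits]
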