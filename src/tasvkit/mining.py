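"""Candidate discovery: extract TE loci with flanks from donor scaffolds, place the
flanks on the reference, and partition loci into insertion/deletion candidates.

Placement uses exact 32-mer anchors near the outer flank end followed by gapless
x-drop extension toward the TE; because donor flanks are (nearly) verbatim copies
of reference sequence, this recovers exact inner breakpoint coordinates. A banded
edlib search is the fallback when no clean anchor exists. A flank that places at
two locations of near-equal identity is rejected as ambiguous rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import edlib
import pandas as pd

from .annotate import AnnotationHit
from .genome import RepeatAnnotation
from .library import ConsensusLibrary
from .sequtil import KmerIndex, max_n_run, xdrop_backward, xdrop_forward

PLACEMENT_K = 32
MIN_USABLE_FLANK = 200


@dataclass
class Placement:
    contig: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class CandidateLocus:
    locus_id: str
    donor_contig: str
    te_start: int
    te_end: int
    subfamily: str
    family: str
    cons_start: int = 0
    cons_end: int = 0
    te_seq: str = ""
    left_flank: str = ""
    right_flank: str = ""
    left_short: bool = False
    right_short: bool = False
    left_placement: Placement | None = None
    right_placement: Placement | None = None
    kind: str = "UNPLACED"   # then INSERTION_CANDIDATE | DELETION_CANDIDATE | REJECTED
    reason: str = ""
    gap_in_reference: int = 0
    overlap_in_reference: int = 0
    deletion_track: str = ""

    @property
    def te_len(self) -> int:
        return self.te_end - self.te_start


def extract_loci(donor_annotations: list[AnnotationHit] | list[RepeatAnnotation],
                 donor_genome: Mapping[str, str], subfamilies: set[str],
                 flank_len: int = 2000, merge_gap: int = 5) -> list[CandidateLocus]:
    """One locus per donor TE copy of the requested subfamilies, with flanks.

    Adjacent same-subfamily hits separated by <= ``merge_gap`` bp are merged into
    a single locus: a structured element (e.g. an LTR-internal-LTR copy, or a
    junction-split copy) must surface as one candidate, not several.
    """
    if not 500 <= flank_len <= 4000:
        raise ValueError("flank_len must be within [500, 4000]")
    selected = sorted(
        (a for a in donor_annotations if a.subfamily in subfamilies),
        key=lambda a: (a.contig, a.start))
    merged: list[list] = []
    for ann in selected:
        if (merged and merged[-1][0] == ann.contig
                and ann.subfamily == merged[-1][3]
                and ann.start - merged[-1][2] <= merge_gap):
            merged[-1][2] = max(merged[-1][2], ann.end)
            merged[-1][4] = min(merged[-1][4], ann.cons_start)
            merged[-1][5] = max(merged[-1][5], ann.cons_end)
        else:
            merged.append([ann.contig, ann.start, ann.end, ann.subfamily,
                           ann.cons_start, ann.cons_end])
    loci = []
    for i, (contig, start, end, subfamily, c0, c1) in enumerate(merged):
        seq = donor_genome[contig]
        lf_start = max(0, start - flank_len)
        rf_end = min(len(seq), end + flank_len)
        loci.append(CandidateLocus(
            locus_id=f"locus{i:05d}", donor_contig=contig,
            te_start=start, te_end=end, subfamily=subfamily,
            family="", cons_start=c0, cons_end=c1, te_seq=seq[start:end],
            left_flank=seq[lf_start:start], right_flank=seq[end:rf_end],
            left_short=start - lf_start < flank_len,
            right_short=rf_end - end < flank_len,
        ))
    return loci


class ReferenceIndex:
    """Exact 32-mer index over every reference contig, for anchored placement."""

    def __init__(self, contigs: Mapping[str, str], k: int = PLACEMENT_K):
        self.k = k
        self.contigs = dict(contigs)
        self._indexes = {name: KmerIndex(seq, k) for name, seq in self.contigs.items()}

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        from .sequtil import encode, kmer_hashes
        h = kmer_hashes(encode(kmer), self.k)
        if len(h) != 1:
            return []
        out = []
        for name, idx in self._indexes.items():
            for pos in idx.lookup(int(h[0])):
                out.append((name, int(pos)))
        return out


def _anchor_placement(flank: str, ref_index: ReferenceIndex, inner: str,
                      anchor_offsets=(0, 64, 160, 320, 640, 1200),
                      max_anchor_hits: int = 12) -> list[Placement]:
    """Candidate placements of a flank via exact outer anchors.

    ``inner`` is 'right' for a left flank (TE on its right) and 'left' for a
    right flank. Returns one placement per anchored location; the inner interval
    boundary is determined by gapless x-drop extension toward the TE.
    """
    n = len(flank)
    for off in anchor_offsets:
        if off + PLACEMENT_K > n:
            break
        a = off if inner == "right" else n - PLACEMENT_K - off
        kmer = flank[a:a + PLACEMENT_K]
        hits = ref_index.lookup(kmer)
        if not hits or len(hits) > max_anchor_hits:
            continue
        placements = []
        for contig, p in hits:
            ref = ref_index.contigs[contig]
            out_ext = xdrop_backward(ref, p, flank, a)
            in_ext = xdrop_forward(ref, p + PLACEMENT_K, flank, a + PLACEMENT_K)
            start = p - out_ext
            end = p + PLACEMENT_K + in_ext
            covered = end - start
            mm = sum(1 for i in range(covered)
                     if ref[start + i] != flank[a - out_ext + i])
            identity = (covered - mm) / max(1, n)
            placements.append(Placement(contig, start, end, "+", round(identity, 4)))
        if placements:
            return placements
    return []


def _edlib_placement(flank: str, ref_index: ReferenceIndex,
                     max_div: float = 0.08) -> list[Placement]:
    """Fallback banded search of the whole flank against every contig."""
    k = max(8, int(max_div * len(flank)))
    placements = []
    for contig, ref in ref_index.contigs.items():
        res = edlib.align(flank, ref, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        s, e = res["locations"][0]
        identity = 1.0 - res["editDistance"] / len(flank)
        placements.append(Placement(contig, s, e + 1, "+", round(identity, 4)))
        # probe for a second, disjoint placement to judge ambiguity
        masked = ref[:s] + "N" * (e + 1 - s) + ref[e + 1:]
        res2 = edlib.align(flank, masked, mode="HW", task="locations", k=k)
        if res2["editDistance"] >= 0:
            s2, e2 = res2["locations"][0]
            placements.append(Placement(contig, s2, e2 + 1, "+",
                                        round(1.0 - res2["editDistance"] / len(flank), 4)))
    return placements


def _place_one(flank: str, ref_index: ReferenceIndex, inner: str,
               min_identity: float, margin: float) -> tuple[Placement | None, str]:
    if len(flank) < MIN_USABLE_FLANK:
        return None, "short flank"
    placements = _anchor_placement(flank, ref_index, inner)
    if not placements:
        placements = _edlib_placement(flank, ref_index)
    placements = [p for p in placements if p.identity >= min_identity]
    if not placements:
        return None, "no placement"
    placements.sort(key=lambda p: (-p.identity, p.contig, p.start))
    best = placements[0]
    for other in placements[1:]:
        disjoint = (other.contig != best.contig
                    or other.end <= best.start or other.start >= best.end)
        if disjoint and best.identity - other.identity <= margin:
            return None, "ambiguous"
    return best, ""


def place_flanks(locus: CandidateLocus, ref_index: ReferenceIndex,
                 min_identity: float = 0.95,
                 ambiguity_margin: float = 0.02) -> CandidateLocus:
    """Assign each flank its best unique reference placement, or reject the locus."""
    left, left_reason = _place_one(locus.left_flank, ref_index, "right",
                                   min_identity, ambiguity_margin)
    right, right_reason = _place_one(locus.right_flank, ref_index, "left",
                                     min_identity, ambiguity_margin)
    locus.left_placement, locus.right_placement = left, right
    if left is None or right is None:
        locus.kind = "REJECTED"
        locus.reason = "; ".join(
            f"{side} flank: {r}" for side, r in
            (("left", left_reason), ("right", right_reason)) if r)
    return locus


def call_candidates(placed_loci: list[CandidateLocus], min_insertion_len: int = 100,
                    adjacency_gap: int = 50,
                    max_tsd_overlap: int = 45) -> list[CandidateLocus]:
    """Partition placed loci into insertion/deletion candidates (exhaustively).

    Insertions: flank placements adjacent or overlapping in the reference
    (gap <= ``adjacency_gap``) and donor TE >= ``min_insertion_len`` bp (the
    <100 bp candidates are filtered out). Deletions: co-linear placements with a
    larger gap; no size selection. Loci carrying N-stretches (>=5 consecutive N)
    anywhere are dropped as ambiguous sequence.
    """
    for locus in placed_loci:
        if locus.kind == "REJECTED":
            continue
        if locus.left_placement is None or locus.right_placement is None:
            locus.kind, locus.reason = "REJECTED", "unplaced flank"
            continue
        if max(max_n_run(locus.te_seq), max_n_run(locus.left_flank),
               max_n_run(locus.right_flank)) >= 5:
            locus.kind, locus.reason = "REJECTED", "ambiguous sequence"
            continue
        lp, rp = locus.left_placement, locus.right_placement
        if lp.contig != rp.contig or lp.strand != rp.strand:
            locus.kind, locus.reason = "REJECTED", "inconsistent placement"
            continue
        gap = rp.start - lp.end
        if gap < -max_tsd_overlap:
            locus.kind, locus.reason = "REJECTED", "inconsistent placement"
            continue
        locus.gap_in_reference = max(0, gap)
        locus.overlap_in_reference = max(0, -gap)
        if gap <= adjacency_gap:
            if locus.te_len >= min_insertion_len:
                locus.kind = "INSERTION_CANDIDATE"
            else:
                locus.kind, locus.reason = "REJECTED", "short insertion"
        else:
            locus.kind = "DELETION_CANDIDATE"
    return placed_loci


def filter_concordant(candidates: list[CandidateLocus],
                      ref_annotations: list[RepeatAnnotation],
                      library: ConsensusLibrary) -> list[CandidateLocus]:
    """Drop loci whose reference gap holds a matching copy of the same element.

    A donor TE whose flank placements bracket a same-family reference annotation
    of (nearly) the same length is a copy shared by both genomes, not a variant.
    """
    by_contig: dict[str, list[RepeatAnnotation]] = {}
    for ann in ref_annotations:
        by_contig.setdefault(ann.contig, []).append(ann)
    for anns in by_contig.values():
        anns.sort(key=lambda a: a.start)
    for locus in candidates:
        if locus.kind != "DELETION_CANDIDATE":
            continue
        lp, rp = locus.left_placement, locus.right_placement
        gap_start, gap_end = lp.end, rp.start
        gap = gap_end - gap_start
        tol = max(25, int(0.08 * locus.te_len))
        if abs(gap - locus.te_len) > tol:
            continue
        fam = library.family_of(locus.subfamily) if locus.subfamily in library else ""
        for ann in by_contig.get(lp.contig, ()):
            if ann.start >= gap_end:
                break
            if ann.end <= gap_start:
                continue
            cover = min(ann.end, gap_end) - max(ann.start, gap_start)
            same_family = (library.family_of(ann.subfamily) == fam) if fam else True
            if same_family and cover >= 0.8 * gap and abs(len(ann) - locus.te_len) <= tol:
                locus.kind, locus.reason = "REJECTED", "concordant reference copy"
                break
    return candidates


def dedupe_deletion_candidates(candidates: list[CandidateLocus]) -> list[CandidateLocus]:
    """Collapse deletion candidates that describe the same junction.

    A rearranged junction can surface once per retained partner remnant (two loci
    whose placement gaps both bracket the same deleted interval). Candidates are
    duplicates when their gap intersection covers >= 90% of the smaller estimated
    deletion (gap minus donor TE length); the locus with the longer donor TE
    (usually the merged junction) is kept.
    """
    dels = sorted((c for c in candidates if c.kind == "DELETION_CANDIDATE"),
                  key=lambda c: (c.left_placement.contig, c.left_placement.end,
                                 -c.te_len))
    kept: list[CandidateLocus] = []
    for cand in dels:
        lp, rp = cand.left_placement, cand.right_placement
        est = max(1, cand.gap_in_reference - cand.te_len)
        dup = None
        for other in kept:
            if other.left_placement.contig != lp.contig:
                continue
            inter = (min(rp.start, other.right_placement.start)
                     - max(lp.end, other.left_placement.end))
            other_est = max(1, other.gap_in_reference - other.te_len)
            if inter >= 0.9 * min(est, other_est):
                dup = other
                break
        if dup is None:
            kept.append(cand)
        else:
            cand.kind = "REJECTED"
            cand.reason = f"duplicate junction (also mined as {dup.locus_id})"
    return candidates


def require_deletion_flank_repeats(candidate: CandidateLocus,
                                   reference_annotations: list[RepeatAnnotation],
                                   library: ConsensusLibrary,
                                   flank_len: int = 2000) -> tuple[bool, str]:
    """Keep a deletion candidate only when both breakpoint flanks anchor repeats
    of the same family (Alu-Alu -> ARMD track, L1-L1 -> L1RAD track).

    The breakpoints lie inside the reference gap (part of the recombinant copies
    is retained in the donor), so each window spans the outer flank plus the
    donor-TE-sized margin of the gap on its side.
    """
    if candidate.kind != "DELETION_CANDIDATE":
        raise ValueError("flank-repeat rule applies to deletion candidates only")
    lp, rp = candidate.left_placement, candidate.right_placement
    te_len = candidate.te_len
    left_lo, left_hi = lp.end - flank_len, min(lp.end + te_len, rp.start)
    right_lo, right_hi = max(rp.start - te_len, lp.end), rp.start + flank_len

    def families(lo: int, hi: int) -> set[str]:
        fams = set()
        for ann in reference_annotations:
            if ann.contig == lp.contig and ann.start < hi and ann.end > lo:
                fams.add(library.family_of(ann.subfamily))
        return fams

    shared = families(left_lo, left_hi) & families(right_lo, right_hi)
    if not shared:
        candidate.deletion_track = ""
        return False, ""
    # prefer the recombinogenic families the source tracks are named for
    for fam, track in (("Alu", "ARMD"), ("L1", "L1RAD")):
        if fam in shared:
            candidate.deletion_track = track
            return True, track
    fam = sorted(shared)[0]
    candidate.deletion_track = f"{fam}-track"
    return True, candidate.deletion_track


def loci_to_table(loci: list[CandidateLocus]) -> pd.DataFrame:
    rows = []
    for lc in loci:
        row = {
            "locus_id": lc.locus_id, "donor_contig": lc.donor_contig,
            "te_start": lc.te_start, "te_end": lc.te_end,
            "subfamily": lc.subfamily, "kind": lc.kind, "reason": lc.reason,
            "gap_in_reference": lc.gap_in_reference,
            "overlap_in_reference": lc.overlap_in_reference,
            "deletion_track": lc.deletion_track,
        }
        for side, p in (("left", lc.left_placement), ("right", lc.right_placement)):
            row[f"{side}_contig"] = p.contig if p else "."
            row[f"{side}_start"] = p.start if p else -1
            row[f"{side}_end"] = p.end if p else -1
            row[f"{side}_identity"] = p.identity if p else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
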