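"""Junction analysis: the algorithmic version of manual TASV inspection.

Insertions are classified by their hallmarks — target site duplication (TSD),
poly-A tail, truncation, LTR block structure — into classical insertions, NCAIs
(TSD-less, poly-A-less, target-deleting insertions), solitary LTRs and
HERV-internal-deletion insertions. Deletions are classified NAHR vs NHEJ from the
donor junction: a junction spanned by a single chimeric element whose 5' part
matches the upstream reference copy and 3' part the downstream copy at equivalent
consensus positions is NAHR (homology = the maximal identical stretch both
parental copies share across the crossover); anything else TE-anchored is NHEJ,
with the junction microhomology measured explicitly.

Breakpoint conventions: within a perfect-identity stretch the true breakpoint is
unidentifiable, so NAHR deletion intervals are left-aligned at the homology
stretch start and the crossover is reported as a consensus interval, never a
point; NHEJ deletion intervals are right-aligned (break5 at the last base that
must derive from the upstream side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import edlib
import numpy as np
import pandas as pd

from .genome import RepeatAnnotation
from .library import ConsensusLibrary
from .mining import CandidateLocus
from .sequtil import hamming, lce_backward, lce_forward

MIN_TSD = 5
MAX_TSD = 30
TSD_MAX_MISMATCH_FRAC = 0.10
TSD_WINDOW_PAD = 14
TE_PAD = 6              # element-side bases included in the left TSD window
MIN_TSD_OVERLAP = 3     # placement overlap (bp) required to accept a TSD
MIN_HOMOLOGY = 3
MAX_MICROHOMOLOGY = 30
MIN_JUNCTION_ANCHOR = 20  # bp of reference continuation marking a non-novel junction
TRUNCATION_TOL = 10


@dataclass
class TsdCall:
    seq: str
    mismatches: int
    left_offset: int
    right_offset: int


@dataclass
class JunctionCall:
    locus_id: str
    contig: str
    ref_start: int
    ref_end: int
    mechanism: str
    subfamily: str = ""
    family: str = ""
    inserted_len: int = 0
    deleted_len: int = 0
    tsd_seq: str = ""
    tsd_mismatches: int = 0
    polyA_len: int = 0
    trunc_start: int = -1
    trunc_end: int = -1
    pre_insertion_del_len: int = 0
    homology_len: int = 0
    homology_cons_lo: int = -1
    homology_cons_hi: int = -1
    microhomology_len: int = 0
    partner1: str = ""
    partner2: str = ""
    deletion_track: str = ""
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Hallmark detectors
# ---------------------------------------------------------------------------

def detect_tsd(left_window: str, right_window: str, max_tsd: int = MAX_TSD,
               max_mismatch_frac: float = TSD_MAX_MISMATCH_FRAC,
               min_tsd: int = MIN_TSD, max_left_offset: int = 0,
               max_right_offset: int = 0) -> TsdCall | None:
    """Longest duplicated target sequence across an insertion junction.

    Finds the longest S (min_tsd <= |S| <= max_tsd) such that S ends the left
    junction window and a copy with <= max_mismatch_frac * |S| mismatches begins
    the right junction window; the copy's first and last base must match exactly
    (a duplication is delimited by matching endpoints — tolerating a mismatched
    end base would systematically overcall the TSD by one). Small offsets from
    the window edges may be allowed to absorb junction jitter. Ties: longest
    wins, then fewest mismatches, then smallest (and leftmost) offsets. Returns
    None when nothing qualifies.
    """
    nl, nr = len(left_window), len(right_window)
    if nl < min_tsd or nr < min_tsd:
        return None
    best: tuple[int, int, int, int, str] | None = None  # (-len, mm, loff+roff, roff, seq)
    max_len = min(max_tsd, nl, nr)
    for length in range(max_len, min_tsd - 1, -1):
        allowed = int(max_mismatch_frac * length)
        for loff in range(0, max_left_offset + 1):
            if loff + length > nl:
                continue
            s = left_window[nl - loff - length: nl - loff]
            for roff in range(0, max_right_offset + 1):
                if roff + length > nr:
                    continue
                t = right_window[roff: roff + length]
                if s[0] != t[0] or s[-1] != t[-1]:
                    continue
                mm = hamming(s, t)
                if mm <= allowed:
                    key = (-length, mm, loff + roff, roff, s)
                    if best is None or key < best:
                        best = key
        if best is not None and -best[0] == length:
            break  # no longer candidate can appear
    if best is None:
        return None
    return TsdCall(best[4], best[1], best[2] - best[3], best[3])


def detect_polyA(seq_3prime_junction: str, window: int = 50) -> int:
    """Poly-A tail length at an element 3' end.

    ``seq_3prime_junction`` starts at the element 3' end. Returns the maximal run
    length ell (>= 6) with >= 80% adenine ending on an A; 0 otherwise.
    """
    if window < 10:
        raise ValueError("poly-A window must be >= 10 bp")
    seq = seq_3prime_junction[:window]
    best = 0
    n_a = 0
    for i, c in enumerate(seq, start=1):
        if c == "A":
            n_a += 1
            if i >= 6 and n_a >= 0.8 * i:
                best = i
    return best


def measure_microhomology(donor_junction: str, ref_break5_context: str,
                          ref_break3_context: str,
                          max_mh: int = MAX_MICROHOMOLOGY) -> int:
    """Microhomology at an NHEJ junction (the ambiguous-join definition).

    Longest S that ends ``ref_break5_context`` (reference upstream of break5),
    begins ``ref_break3_context`` (reference downstream of break3) and appears
    exactly once at the donor junction. ``donor_junction`` must be a window with
    the junction point exactly at its midpoint.
    """
    mid = len(donor_junction) // 2
    limit = min(max_mh, len(ref_break5_context), len(ref_break3_context), mid)
    for m in range(limit, 0, -1):
        s = ref_break5_context[-m:]
        if ref_break3_context[:m] != s:
            continue
        window = donor_junction[mid - m: mid + m]
        count = sum(1 for i in range(len(window) - m + 1) if window[i:i + m] == s)
        if count == 1:
            return m
    return 0


def map_crossover_to_consensus(chimera_seq: str, cons_interval: tuple[int, int],
                               upstream_seq: str, upstream_cons_start: int,
                               downstream_seq: str, downstream_cons_start: int
                               ) -> tuple[int, int, bool]:
    """Consensus interval within which an NAHR crossover must lie.

    The chimera matches the upstream parental copy on its 5' side and the
    downstream copy on its 3' side; the crossover can only be localized to the
    stretch where both parents agree with the chimera. All three sequences are
    compared in consensus coordinates (substitution-diverged copies only).
    Returns (lo, hi, flagged); flagged marks an unresolvable crossover (the
    parental copies never disagree over the shared interval).
    """
    c0, c1 = cons_interval

    def at(seq, cons_start, pos):
        i = pos - cons_start
        return seq[i] if 0 <= i < len(seq) else None

    lo_bound, hi_bound = c0, c1
    # first disagreement between chimera and upstream parent, scanning 5'->3'
    hi = hi_bound
    for pos in range(lo_bound, hi_bound):
        a, b = at(chimera_seq, c0, pos), at(upstream_seq, upstream_cons_start, pos)
        if a is None or b is None or a != b:
            hi = pos
            break
    # last disagreement between chimera and downstream parent, scanning 3'->5'
    lo = lo_bound
    for pos in range(hi_bound - 1, lo_bound - 1, -1):
        a, b = at(chimera_seq, c0, pos), at(downstream_seq, downstream_cons_start, pos)
        if a is None or b is None or a != b:
            lo = pos + 1
            break
    if lo <= lo_bound and hi >= hi_bound:
        return lo_bound, hi_bound, True  # identical copies: unresolvable
    if lo > hi:
        return lo, lo, True  # chimera does not align contiguously
    return lo, hi, False


def crossover_tally(intervals: list[tuple[int, int]], consensus_len: int,
                    bin_width: int = 10) -> pd.Series:
    """Bin crossover-interval midpoints along the consensus."""
    n_bins = (consensus_len + bin_width - 1) // bin_width
    counts = np.zeros(n_bins, dtype=int)
    for lo, hi in intervals:
        mid = (lo + hi) // 2
        counts[min(mid // bin_width, n_bins - 1)] += 1
    return pd.Series(counts, index=[i * bin_width for i in range(n_bins)])


# ---------------------------------------------------------------------------
# Insertion classification
# ---------------------------------------------------------------------------

def _ltr_structure(te_seq: str, consensus: str, ltr_block_len: int) -> tuple[str, int]:
    """Classify an LTR-family element's block structure.

    Returns (kind, internal_kept): kind in {"solitary", "internal_del", "full",
    "other"}. The consensus is LTR + internal + LTR with identical blocks.
    """
    ltr = consensus[:ltr_block_len]
    internal_len = len(consensus) - 2 * ltr_block_len
    n = len(te_seq)

    def div(a: str, b: str) -> float:
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return d / max(1, max(len(a), len(b)))

    if abs(n - ltr_block_len) <= 30 and div(te_seq, ltr) <= 0.12:
        return "solitary", 0
    if n >= 2 * ltr_block_len - 30:
        if (div(te_seq[:ltr_block_len], ltr) <= 0.12
                and div(te_seq[-ltr_block_len:], ltr) <= 0.12):
            kept = n - 2 * ltr_block_len
            if kept <= internal_len - 5:
                return "internal_del", max(kept, 0)
            return "full", kept
    return "other", 0


def classify_insertion(candidate: CandidateLocus, tsd_call: TsdCall | None,
                       polyA_len: int, truncation: tuple[int, int],
                       family: str, cons_len: int,
                       ltr_info: tuple[str, int] | None = None,
                       min_tsd_overlap: int = MIN_TSD_OVERLAP,
                       junction: tuple[int, int] | None = None) -> JunctionCall:
    """Mechanism decision for an insertion candidate, rules applied in order:

    1. LTR family, element matches a single LTR block    -> SOLITARY_LTR
    2. LTR family, internal segment partially absent     -> HERV_INTERNAL_DEL
    3. TSD present (string found + placements overlap)   -> CLASSICAL_INS
    4. TSD absent and (no poly-A or element truncated)   -> NCAI
    5. otherwise                                         -> UNCLASSIFIED
    """
    lp, rp = candidate.left_placement, candidate.right_placement
    left_end, right_start = junction if junction else (lp.end, rp.start)
    gap = max(0, right_start - left_end)
    # bases at the element edges that continue the reference belong to the
    # flanks, not the element
    trim = max(0, left_end - lp.end) + max(0, rp.start - right_start)
    te_len = max(0, candidate.te_len - trim)
    trunc_start, trunc_end = truncation
    truncated = trunc_start > TRUNCATION_TOL or trunc_end < cons_len - TRUNCATION_TOL
    notes: list[str] = []
    tsd_present = (tsd_call is not None
                   and candidate.overlap_in_reference >= min_tsd_overlap)
    if tsd_call is not None and not tsd_present:
        notes.append("tsd string without placement overlap: ignored")

    base = dict(locus_id=candidate.locus_id, contig=rp.contig,
                subfamily=candidate.subfamily, family=family,
                trunc_start=trunc_start, trunc_end=trunc_end,
                polyA_len=polyA_len, notes=notes)
    if tsd_present:
        base.update(tsd_seq=tsd_call.seq, tsd_mismatches=tsd_call.mismatches)

    if family == "LTR" and ltr_info is not None:
        kind, _kept = ltr_info
        if kind == "solitary":
            notes.append("element matches a single LTR block")
            return JunctionCall(ref_start=right_start, ref_end=right_start,
                                mechanism="SOLITARY_LTR",
                                inserted_len=te_len, **base)
        if kind == "internal_del":
            notes.append("LTR blocks present, internal segment partially absent")
            return JunctionCall(ref_start=left_end, ref_end=right_start,
                                mechanism="HERV_INTERNAL_DEL",
                                inserted_len=te_len,
                                deleted_len=gap, **base)
    if tsd_present:
        return JunctionCall(ref_start=right_start, ref_end=right_start,
                            mechanism="CLASSICAL_INS",
                            inserted_len=te_len + polyA_len, **base)
    if polyA_len == 0 or truncated:
        notes.append("no TSD" + (", truncated" if truncated else "")
                     + (", no poly-A" if polyA_len == 0 else ""))
        return JunctionCall(ref_start=left_end, ref_end=right_start,
                            mechanism="NCAI", inserted_len=te_len,
                            deleted_len=gap, pre_insertion_del_len=gap, **base)
    notes.append("full-length element with poly-A but no TSD")
    return JunctionCall(ref_start=left_end, ref_end=right_start,
                        mechanism="UNCLASSIFIED", inserted_len=te_len,
                        **base)


def analyze_insertion_candidate(locus: CandidateLocus, donor: Mapping[str, str],
                                library: ConsensusLibrary,
                                max_tsd: int = MAX_TSD, ltr_block_len: int = 450,
                                reference: Mapping[str, str] | None = None
                                ) -> JunctionCall:
    """Glue: derive the hallmark inputs from the donor sequence, then classify.

    When the reference is supplied, the junction coordinates are refined by exact
    common extension: an element annotation that stole a few reference bases at
    either end (possible when the adjoining bases happen to match the consensus)
    is corrected before the target-deletion length is read off.
    """
    donor_seq = donor[locus.donor_contig]
    entry = library[locus.subfamily]
    family = entry.family
    # The tail is located as the maximal pure-A run: the permissive >=80%-adenine
    # rule, applied to an open window, would swallow A-rich TSD sequence and push
    # the TSD search window past the duplication.
    run = lce_forward(donor_seq, locus.te_end, "A" * 60, 0)
    polyA = detect_polyA(donor_seq[locus.te_end: locus.te_end + max(10, run + 1)])
    left_window = donor_seq[max(0, locus.te_start - (max_tsd + TSD_WINDOW_PAD)):
                            locus.te_start + TE_PAD]
    # right TSD copy follows the poly-A tail; back off a few bases in case the
    # tail run absorbed adenines at the TSD start (or, with no tail, in case the
    # element annotation overshot into the TSD)
    rw0 = locus.te_end + max(0, run - 6) if run else max(0, locus.te_end - 4)
    right_window = donor_seq[rw0: rw0 + max_tsd + TSD_WINDOW_PAD]
    # right offsets beyond the back-off would accept copies that do not abut the
    # junction (local tandem repeats near the target site), so they are capped
    tsd_call = detect_tsd(left_window, right_window, max_tsd=max_tsd,
                          max_left_offset=TE_PAD + 6, max_right_offset=8)
    ltr_info = (_ltr_structure(locus.te_seq, entry.sequence, ltr_block_len)
                if family == "LTR" else None)
    truncation = (locus.cons_start, locus.cons_end)
    junction = None
    if reference is not None:
        lp, rp = locus.left_placement, locus.right_placement
        ref_seq = reference[lp.contig]
        eps_l = lce_forward(donor_seq, locus.te_start, ref_seq, lp.end, limit=20)
        eps_r = lce_backward(donor_seq, locus.te_end, ref_seq, rp.start, limit=20)
        junction = (lp.end + eps_l, rp.start - eps_r)
    return classify_insertion(locus, tsd_call, polyA, truncation, family,
                              len(entry), ltr_info, junction=junction)


# ---------------------------------------------------------------------------
# Deletion classification
# ---------------------------------------------------------------------------

def _find_partner(annotations: list[RepeatAnnotation], contig: str,
                  pos: int) -> RepeatAnnotation | None:
    """Annotation containing ``pos`` (or within 5 bp), preferring containment."""
    best = None
    for ann in annotations:
        if ann.contig != contig:
            continue
        if ann.start <= pos < ann.end:
            return ann
        d = max(ann.start - pos, pos - (ann.end - 1), 0)
        if d <= 5 and (best is None or d < best[0]):
            best = (d, ann)
    return best[1] if best else None


def classify_deletion(candidate: CandidateLocus,
                      ref_annotations: list[RepeatAnnotation],
                      reference: Mapping[str, str], donor: Mapping[str, str],
                      library: ConsensusLibrary,
                      min_homology: int = MIN_HOMOLOGY,
                      max_mh: int = MAX_MICROHOMOLOGY) -> JunctionCall:
    """NAHR vs NHEJ decision with homology / microhomology measurement.

    The donor junction is pinned by exact common extension from both flank
    placements; the shared stretch between the two extensions is the junction
    ambiguity. NAHR requires the upstream and downstream partner copies to meet
    at equivalent consensus positions with >= min_homology identical bases;
    otherwise the junction is NHEJ with measured microhomology. A junction whose
    donor element does not continue the reference copies at all is a novel
    insertion, returned UNCLASSIFIED with a note for re-routing.
    """
    lp, rp = candidate.left_placement, candidate.right_placement
    ref = reference[lp.contig]
    donor_seq = donor[candidate.donor_contig]

    i1 = lce_forward(donor_seq, candidate.te_start, ref, lp.end)
    i2 = lce_backward(donor_seq, candidate.te_end, ref, rp.start)
    j1 = candidate.te_start + i1
    r1 = lp.end + i1
    j2 = candidate.te_end - i2
    r3 = rp.start - i2

    base = dict(locus_id=candidate.locus_id, contig=lp.contig,
                subfamily=candidate.subfamily,
                family=(library.family_of(candidate.subfamily)
                        if candidate.subfamily in library else ""),
                deletion_track=candidate.deletion_track)

    # A donor element that continues the reference on neither side is a novel
    # insertion, not a rearranged junction. One short side is legitimate: when a
    # junction locus covers only the upstream remnant, the downstream extension
    # is exactly the junction microhomology.
    if i1 < MIN_JUNCTION_ANCHOR and i2 < MIN_JUNCTION_ANCHOR:
        return JunctionCall(ref_start=lp.end, ref_end=rp.start,
                            mechanism="UNCLASSIFIED",
                            notes=["novel_element: donor element does not continue "
                                   "the reference at either breakpoint"], **base)

    s = j1 - j2
    notes: list[str] = []
    if s < 0:
        if -s <= 10:
            # donor carries a few untemplated bases between the matched segments;
            # the deleted interval [r1, r3) is still pinned by both extensions
            notes.append(f"{-s} bp untemplated junction insertion")
            s = 0
        else:
            return JunctionCall(ref_start=lp.end, ref_end=rp.start,
                                mechanism="UNCLASSIFIED",
                                notes=[f"{-s} bp unexplained junction sequence"], **base)

    annU = _find_partner(ref_annotations, lp.contig, max(r1 - 1, 0))
    annD = _find_partner(ref_annotations, lp.contig, r3 + s)
    partner1 = annU.subfamily if annU else ""
    partner2 = annD.subfamily if annD else ""
    base.update(partner1=partner1, partner2=partner2)

    nahr_possible = (
        annU is not None and annD is not None
        and annU.strand == "+" and annD.strand == "+"
        and library.family_of(annU.subfamily) == library.family_of(annD.subfamily)
    )
    if nahr_possible:
        consU = annU.cons_start + (r1 - annU.start)
        consD = annD.cons_start + ((r3 + s) - annD.start)
        if abs(consU - consD) <= 3 and s >= min_homology:
            lo, hi = consU - s, consU
            return JunctionCall(ref_start=r1 - s, ref_end=r3,
                                mechanism="NAHR_DEL", deleted_len=r3 - (r1 - s),
                                homology_len=s, homology_cons_lo=lo,
                                homology_cons_hi=hi,
                                notes=notes + ["chimeric junction at equivalent "
                                               "consensus positions"], **base)

    K = max_mh
    junction_window = donor_seq[j1 - K: j1 + K]
    measured = measure_microhomology(junction_window, ref[max(0, r1 - 2 * K): r1],
                                     ref[r3: r3 + 2 * K], max_mh=K)
    if measured != s:
        notes.append(f"junction ambiguity {s} bp vs context microhomology {measured} bp")
    return JunctionCall(ref_start=r1, ref_end=r3 + s,
                        mechanism="NHEJ_DEL", deleted_len=(r3 + s) - r1,
                        microhomology_len=measured, notes=notes, **base)


# ---------------------------------------------------------------------------
# Call table serialization
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "locus_id", "contig", "ref_start", "ref_end", "mechanism", "subfamily",
    "family", "inserted_len", "deleted_len", "tsd_seq", "tsd_mismatches",
    "polyA_len", "trunc_start", "trunc_end", "pre_insertion_del_len",
    "homology_len", "homology_cons_lo", "homology_cons_hi", "microhomology_len",
    "partner1", "partner2", "deletion_track", "notes",
]


def calls_to_table(calls: list[JunctionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {col: getattr(c, col) for col in CALL_COLUMNS}
        row["tsd_seq"] = c.tsd_seq if c.tsd_seq else "."
        row["notes"] = "; ".join(c.notes) if c.notes else "."
        for col in ("subfamily", "family", "partner1", "partner2", "deletion_track"):
            row[col] = row[col] if row[col] else "."
        rows.append(row)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
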