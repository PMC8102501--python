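"""Benchmarking calls against a simulation's ground truth.

Truth events and called junctions are matched by proximity on the reference; the
simulator keeps events several kilobases apart, so matching is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import JunctionCall
from .genome import TASVEvent
from .mining import CandidateLocus


def expected_candidate_kind(event: TASVEvent, adjacency_gap: int = 50) -> str:
    """The mining class a truth event should surface as."""
    if event.mechanism in ("CLASSICAL_INS", "SOLITARY_LTR"):
        return "INSERTION_CANDIDATE"
    if event.mechanism == "NCAI":
        return ("INSERTION_CANDIDATE" if event.deleted_len <= adjacency_gap
                else "DELETION_CANDIDATE")
    return "DELETION_CANDIDATE"  # NAHR, NHEJ, HERV internal deletion


def _mid(a: int, b: int) -> float:
    return (a + b) / 2.0


@dataclass
class MiningMetrics:
    recall: float
    precision: float
    n_truth: int
    n_candidates: int
    n_matched: int
    missed: list[str] = field(default_factory=list)
    spurious: list[str] = field(default_factory=list)


def evaluate_mining(loci: list[CandidateLocus], truth: list[TASVEvent],
                    adjacency_gap: int = 50, slack: int = 250) -> MiningMetrics:
    """Candidate-level recall/precision against the truth table.

    A candidate matches a truth event when it sits on the same reference contig
    and the event midpoint lies within the candidate's placement gap (padded by
    ``slack``); one-to-one by construction since events are far apart.
    """
    candidates = [l for l in loci
                  if l.kind in ("INSERTION_CANDIDATE", "DELETION_CANDIDATE")]
    matched_truth: set[str] = set()
    matched_cand: set[str] = set()
    for ev in truth:
        mid = _mid(ev.ref_start, ev.ref_end)
        for cand in candidates:
            lp, rp = cand.left_placement, cand.right_placement
            if (lp.contig == ev.contig and cand.locus_id not in matched_cand
                    and lp.end - slack <= mid <= rp.start + slack):
                matched_truth.add(ev.event_id)
                matched_cand.add(cand.locus_id)
                break
    recall = len(matched_truth) / len(truth) if truth else 1.0
    precision = len(matched_cand) / len(candidates) if candidates else 1.0
    return MiningMetrics(
        recall=recall, precision=precision, n_truth=len(truth),
        n_candidates=len(candidates), n_matched=len(matched_truth),
        missed=[e.event_id for e in truth if e.event_id not in matched_truth],
        spurious=[c.locus_id for c in candidates if c.locus_id not in matched_cand],
    )


@dataclass
class ClassificationMetrics:
    accuracy: float
    per_mechanism_accuracy: dict[str, float]
    tsd_exact_fraction: float
    homology_exact_fraction: float
    microhomology_exact_fraction: float
    n_events: int
    n_called: int
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)


def evaluate_classification(calls: list[JunctionCall], truth: list[TASVEvent],
                            slack: int = 350) -> ClassificationMetrics:
    """Mechanism recovery and hallmark exactness against the truth table.

    A call matches a truth event when their reference midpoints are within
    ``slack`` bp on the same contig (NAHR breakpoint conventions can differ from
    the truth coordinates by up to the homology length). An unmatched truth
    event counts as a misclassification.
    """
    used: set[int] = set()
    confusion: dict[tuple[str, str], int] = {}
    per_mech: dict[str, list[int]] = {}
    tsd_ok, tsd_n = 0, 0
    hom_ok, hom_n = 0, 0
    mh_ok, mh_n = 0, 0

    for ev in truth:
        mid = _mid(ev.ref_start, ev.ref_end)
        best = None
        for i, call in enumerate(calls):
            if i in used or call.contig != ev.contig:
                continue
            d = abs(_mid(call.ref_start, call.ref_end) - mid)
            if d <= slack and (best is None or d < best[0]):
                best = (d, i)
        called_mech = "MISSED"
        if best is not None:
            used.add(best[1])
            call = calls[best[1]]
            called_mech = call.mechanism
            if ev.mechanism == "CLASSICAL_INS":
                tsd_n += 1
                tsd_ok += int(call.tsd_seq == ev.tsd)
            if ev.mechanism == "NAHR_DEL":
                hom_n += 1
                hom_ok += int(call.homology_len == ev.homology_len)
            if ev.mechanism == "NHEJ_DEL":
                mh_n += 1
                mh_ok += int(call.microhomology_len == ev.microhomology_len)
        confusion[(ev.mechanism, called_mech)] = confusion.get(
            (ev.mechanism, called_mech), 0) + 1
        per_mech.setdefault(ev.mechanism, []).append(int(called_mech == ev.mechanism))

    n_ok = sum(sum(v) for v in per_mech.values())
    return ClassificationMetrics(
        accuracy=n_ok / len(truth) if truth else 1.0,
        per_mechanism_accuracy={m: sum(v) / len(v) for m, v in per_mech.items()},
        tsd_exact_fraction=tsd_ok / tsd_n if tsd_n else 1.0,
        homology_exact_fraction=hom_ok / hom_n if hom_n else 1.0,
        microhomology_exact_fraction=mh_ok / mh_n if mh_n else 1.0,
        n_events=len(truth), n_called=len(calls), confusion=confusion,
    )
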