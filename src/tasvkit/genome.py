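"""Synthetic genome simulator: a toy reference seeded with diverged TE copies and a
donor ("personal") genome derived from it by six TASV mechanisms, with ground truth.

Mechanisms and their engineered hallmarks:

* CLASSICAL_INS      target site duplication (TSD) flanking the element, poly-A tail,
                     optional 5' truncation.
* NCAI               non-classical insertion: truncated element, no TSD, no poly-A,
                     deletion of the pre-insertion target sequence.
* SOLITARY_LTR       a single LTR block inserted with a TSD at an empty site.
* HERV_INTERNAL_DEL  an LTR-(partial internal)-LTR structure replacing a site that
                     carries only a solitary LTR in the reference.
* NAHR_DEL           recombination between two same-family copies, fusing them into a
                     single chimeric element; an identical homology stretch straddles
                     the crossover, bounded by engineered mismatches so its length is
                     exactly the requested value.
* NHEJ_DEL           end joining of two TE-anchored breaks; the bases immediately
                     upstream of both breakpoints are made identical (the
                     microhomology), again bounded by engineered mismatches.

Truth coordinates are always ORIGINAL reference coordinates; donor sequences are
composed by applying the per-contig edits right-to-left so earlier coordinates
remain valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_bed, write_fasta, BedRecord
from .library import ConsensusLibrary, default_library, LTR_BLOCK_LEN, HERV_INTERNAL_LEN
from .sequtil import mutate_substitutions, random_seq, revcomp

MECHANISMS = (
    "CLASSICAL_INS",
    "NCAI",
    "SOLITARY_LTR",
    "HERV_INTERNAL_DEL",
    "NAHR_DEL",
    "NHEJ_DEL",
)

INSERTION_MECHANISMS = {"CLASSICAL_INS", "NCAI", "SOLITARY_LTR", "HERV_INTERNAL_DEL"}
DELETION_MECHANISMS = {"NAHR_DEL", "NHEJ_DEL"}
# mechanisms whose edit duplicates the target site (one extra TSD copy in the donor)
TSD_MECHANISMS = {"CLASSICAL_INS", "SOLITARY_LTR"}


class GenerationError(RuntimeError):
    pass


@dataclass
class RepeatAnnotation:
    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    cons_start: int
    cons_end: int
    divergence: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad annotation interval [{self.start},{self.end})")
        if not 0 <= self.cons_start < self.cons_end:
            raise ValueError("bad consensus interval")
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError("divergence must be a percentage in [0,100]")

    def __len__(self):
        return self.end - self.start


@dataclass
class GeneFeature:
    contig: str
    start: int
    end: int
    gene: str
    feature: str  # UTR5 | exon | intron | UTR3


@dataclass
class ReferenceGenome:
    contigs: dict[str, str]
    annotations: list[RepeatAnnotation] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)

    def validate(self) -> "ReferenceGenome":
        for ann in self.annotations:
            if ann.contig not in self.contigs:
                raise ValueError(f"annotation on unknown contig {ann.contig}")
            if ann.end > len(self.contigs[ann.contig]):
                raise ValueError(f"annotation beyond contig end: {ann}")
        return self


@dataclass
class TASVEvent:
    event_id: str
    mechanism: str
    contig: str
    ref_start: int
    ref_end: int           # == ref_start for pure insertion points
    inserted_len: int = 0
    deleted_len: int = 0
    tsd: str = ""
    polyA_len: int = 0
    trunc_start: int = -1  # consensus interval actually inserted; -1/-1 when n/a
    trunc_end: int = -1
    homology_len: int = 0
    microhomology_len: int = 0
    subfamily1: str = ""
    subfamily2: str = ""
    cons_breakpoint: int = -1

    @property
    def net_change(self) -> int:
        """Signed donor-minus-reference bp contribution of this event."""
        tsd_gain = len(self.tsd) if self.mechanism in TSD_MECHANISMS else 0
        return self.inserted_len + tsd_gain - self.deleted_len


EVENT_COLUMNS = [
    "event_id", "mechanism", "contig", "ref_start", "ref_end",
    "inserted_len", "deleted_len", "tsd", "polyA_len",
    "trunc_start", "trunc_end", "homology_len", "microhomology_len",
    "subfamily1", "subfamily2", "cons_breakpoint",
]


_EVENT_STR_COLUMNS = ("event_id", "mechanism", "contig", "tsd", "subfamily1",
                      "subfamily2")


def events_to_table(events: list[TASVEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {c: getattr(ev, c) for c in EVENT_COLUMNS}
        for c in ("tsd", "subfamily1", "subfamily2"):
            row[c] = row[c] if row[c] else "."
        rows.append(row)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def table_to_events(table: pd.DataFrame) -> list[TASVEvent]:
    events = []
    for _, row in table.iterrows():
        kwargs = {c: row[c] for c in EVENT_COLUMNS}
        for c in EVENT_COLUMNS:
            if c in _EVENT_STR_COLUMNS:
                val = str(kwargs[c])
                if c in ("tsd", "subfamily1", "subfamily2") and val in (".", "nan"):
                    val = ""
                kwargs[c] = val
            else:
                kwargs[c] = int(kwargs[c])
        events.append(TASVEvent(**kwargs))
    return events


# ---------------------------------------------------------------------------
# Interval reservations (simulation hygiene: planted features never overlap)
# ---------------------------------------------------------------------------

class _Reservations:
    """Non-overlapping interval bookkeeping with per-interval exclusion padding."""

    def __init__(self, length: int):
        self.length = length
        self.intervals: list[tuple[int, int, int]] = []  # (start, end, pad), sorted
        self._starts: list[int] = []
        self._maxspan = 0

    _MAX_PAD = 4096  # upper bound on any exclusion padding used by the simulator

    def conflicts(self, start: int, end: int, pad: int) -> bool:
        import bisect
        if pad > self._MAX_PAD:
            raise ValueError("padding exceeds reservation bound")
        lo = bisect.bisect_left(self._starts, start - self._maxspan - self._MAX_PAD)
        for s, e, p in self.intervals[lo:]:
            if s >= end + self._MAX_PAD:
                break
            gap = max(p, pad)
            if s < end + gap and start < e + gap:
                return True
        return False

    def add(self, start: int, end: int, pad: int) -> None:
        import bisect
        i = bisect.bisect_left(self._starts, start)
        self.intervals.insert(i, (start, end, pad))
        self._starts.insert(i, start)
        self._maxspan = max(self._maxspan, end - start + pad)

    def try_place(self, rng: np.random.Generator, span: int, pad: int,
                  margin: int, tries: int = 400) -> int | None:
        lo, hi = margin, self.length - margin - span
        if hi <= lo:
            return None
        for _ in range(tries):
            start = int(rng.integers(lo, hi))
            if not self.conflicts(start, start + span, pad):
                self.add(start, start + span, pad)
                return start
        return None


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

_OLD_ALU_WEIGHTS = {
    "AluSx": 0.25, "AluSz6": 0.16, "AluSq2": 0.15, "AluSp": 0.14,
    "AluY": 0.10, "AluJb": 0.12, "AluJo": 0.08,
}
_OLD_L1_WEIGHTS = {"L1PA3": 0.6, "L1PA5": 0.4}


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    p = np.asarray([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=p / p.sum()))]


class _Builder:
    """Mutable reference genome under construction."""

    def __init__(self, rng: np.random.Generator, n_contigs: int, length: int,
                 library: ConsensusLibrary):
        self.rng = rng
        self.library = library
        self.names = [f"chr{i + 1}" for i in range(n_contigs)]
        self.arrays = {n: np.frombuffer(random_seq(rng, length).encode(), dtype="S1").copy()
                       for n in self.names}
        self.res = {n: _Reservations(length) for n in self.names}
        self.annotations: list[RepeatAnnotation] = []
        self.genes: list[GeneFeature] = []

    def copy_seq(self, subfamily: str, cons_start: int, cons_end: int,
                 divergence: float, strand: str = "+") -> str:
        cons = self.library[subfamily].sequence[cons_start:cons_end]
        n_subs = int(round(divergence / 100.0 * len(cons)))
        seq = mutate_substitutions(self.rng, cons, n_subs)
        return revcomp(seq) if strand == "-" else seq

    def plant(self, contig: str, pos: int, subfamily: str, cons_start: int,
              cons_end: int, divergence: float, strand: str = "+") -> RepeatAnnotation:
        seq = self.copy_seq(subfamily, cons_start, cons_end, divergence, strand)
        arr = self.arrays[contig]
        arr[pos:pos + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
        ann = RepeatAnnotation(contig, pos, pos + len(seq), strand, subfamily,
                               cons_start, cons_end, divergence)
        self.annotations.append(ann)
        return ann

    def planted_bp(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for ann in self.annotations:
            fam = self.library.family_of(ann.subfamily)
            totals[fam] = totals.get(fam, 0) + len(ann)
        return totals

    def base(self, contig: str, pos: int) -> str:
        return self.arrays[contig][pos].decode()

    def set_base(self, contig: str, pos: int, base: str) -> None:
        self.arrays[contig][pos] = base.encode()

    def force_mismatch(self, contig: str, pos_keep: int, pos_edit: int) -> None:
        """Edit the base at pos_edit so it differs from the base at pos_keep."""
        keep = self.base(contig, pos_keep)
        if self.base(contig, pos_edit) == keep:
            alternatives = [b for b in "ACGT" if b != keep]
            self.set_base(contig, pos_edit, alternatives[int(self.rng.integers(3))])

    def freeze(self) -> ReferenceGenome:
        contigs = {n: a.tobytes().decode() for n, a in self.arrays.items()}
        anns = sorted(self.annotations, key=lambda a: (a.contig, a.start))
        return ReferenceGenome(contigs, anns, self.genes).validate()


def _plant_background(builder: _Builder, te_density: dict[str, float],
                      young_fraction: float) -> None:
    rng = builder.rng
    lib = builder.library
    total_len = sum(len(a) for a in builder.arrays.values())
    planted = builder.planted_bp()
    young_alu = [e.name for e in lib.by_family("Alu") if e.young]
    sva_names = [e.name for e in lib.by_family("SVA")]

    for family, density in te_density.items():
        target = int(density * total_len)
        failures = 0
        while planted.get(family, 0) < target:
            strand = "+" if rng.random() < 0.5 else "-"
            if family == "Alu":
                if rng.random() < young_fraction and young_alu:
                    sub = young_alu[int(rng.integers(len(young_alu)))]
                    div = float(rng.uniform(1.0, 3.0))
                else:
                    sub = _weighted_choice(rng, _OLD_ALU_WEIGHTS)
                    div = float(rng.uniform(5.0, 20.0))
                L = len(lib[sub])
                c0 = 0 if rng.random() < 0.85 else int(rng.integers(10, 150))
                c1 = L
            elif family == "L1":
                if rng.random() < 0.05:
                    sub, div = "L1HS", float(rng.uniform(1.0, 3.0))
                    keep = int(rng.integers(500, 1200))
                else:
                    sub = _weighted_choice(rng, _OLD_L1_WEIGHTS)
                    div = float(rng.uniform(5.0, 20.0))
                    keep = int(math.exp(rng.uniform(math.log(500), math.log(6000))))
                L = len(lib[sub])
                c0, c1 = L - min(keep, L), L  # L1 copies are 5'-truncated
            elif family == "SVA":
                sub = sva_names[int(rng.integers(len(sva_names)))]
                div = float(rng.uniform(1.0, 8.0))
                L = len(lib[sub])
                c0 = 0 if rng.random() < 0.6 else int(rng.integers(50, 600))
                c1 = L
            elif family == "LTR":
                sub, div = "HERV-K", float(rng.uniform(2.0, 10.0))
                if rng.random() < 0.7:
                    c0, c1 = 0, LTR_BLOCK_LEN          # solitary LTR
                else:
                    c0, c1 = 0, len(lib[sub])          # full structure
            else:
                raise GenerationError(f"unknown TE family in density spec: {family}")

            span = c1 - c0
            contig = builder.names[int(rng.integers(len(builder.names)))]
            pos = builder.res[contig].try_place(rng, span, pad=30, margin=200, tries=40)
            if pos is None:
                failures += 1
                if failures > 2000:
                    raise GenerationError(
                        f"cannot reach requested {family} density {density}: genome too full"
                    )
                continue
            builder.plant(contig, pos, sub, c0, c1, div, strand)
            planted[family] = planted.get(family, 0) + span


def _plan_genes(builder: _Builder, gene_fraction: float) -> None:
    if gene_fraction <= 0:
        return
    rng = builder.rng
    gi = 0
    for contig, arr in builder.arrays.items():
        length = len(arr)
        target = int(gene_fraction * length)
        covered = 0
        res = _Reservations(length)
        failures = 0
        while covered < target and failures < 500:
            span = int(math.exp(rng.uniform(math.log(3000), math.log(30000))))
            pos = res.try_place(rng, span, pad=100, margin=100, tries=30)
            if pos is None:
                failures += 1
                continue
            gi += 1
            name = f"gene{gi}"
            end = pos + span
            utr5, utr3 = 200, 400
            builder.genes.append(GeneFeature(contig, pos, pos + utr5, name, "UTR5"))
            cur = pos + utr5
            body_end = end - utr3
            while cur < body_end:
                exon_len = min(150, body_end - cur)
                builder.genes.append(GeneFeature(contig, cur, cur + exon_len, name, "exon"))
                cur += exon_len
                if cur >= body_end:
                    break
                intron_len = min(int(rng.integers(800, 3000)), body_end - cur)
                builder.genes.append(GeneFeature(contig, cur, cur + intron_len, name, "intron"))
                cur += intron_len
            builder.genes.append(GeneFeature(contig, body_end, end, name, "UTR3"))
            covered += span


def build_reference(length_per_contig: int, n_contigs: int = 1,
                    te_density: dict[str, float] | None = None,
                    gene_fraction: float = 0.0, seed: int = 0,
                    library: ConsensusLibrary | None = None,
                    young_fraction: float = 0.15) -> ReferenceGenome:
    """Generate a reference genome with planted, non-overlapping TE copies.

    Old-subfamily copies carry 5-20% divergence, young copies 0.5-3%; annotations
    record the exact planted coordinates and consensus intervals. Gene intervals
    with UTR/exon/intron sub-features cover approximately ``gene_fraction``.
    """
    te_density = dict(te_density or {})
    if sum(te_density.values()) >= 0.9:
        raise GenerationError("TE density fractions must sum to < 0.9")
    library = library or default_library()
    rng = np.random.default_rng(seed)
    builder = _Builder(rng, n_contigs, length_per_contig, library)
    _plant_background(builder, te_density, young_fraction)
    _plan_genes(builder, gene_fraction)
    return builder.freeze()


# ---------------------------------------------------------------------------
# Single-event donor edits (public operations; pure with respect to the genome
# except apply_nhej_deletion, which must engineer the reference context first)
# ---------------------------------------------------------------------------

def _check_site(genome: ReferenceGenome, contig: str, pos: int) -> str:
    if contig not in genome.contigs:
        raise ValueError(f"unknown contig {contig!r}")
    seq = genome.contigs[contig]
    if not 0 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside contig {contig} (len {len(seq)})")
    return seq


def apply_classical_insertion(genome: ReferenceGenome, contig: str, site: int,
                              subfamily: str, tsd_len: int, trunc_5p: int,
                              polyA_len: int, library: ConsensusLibrary,
                              seed: int = 0, divergence: float = 0.0,
                              event_id: str = "ev") -> tuple[str, TASVEvent]:
    """Insert a (possibly 5'-truncated) element with poly-A tail and TSD at ``site``.

    Donor structure: left-TSD + element + poly-A + right-TSD, where both TSD copies
    equal the reference target sequence ref[site:site+tsd_len].
    """
    ref = _check_site(genome, contig, site)
    if tsd_len < 0 or site + tsd_len > len(ref):
        raise ValueError("TSD window outside contig")
    cons = library[subfamily].sequence
    if trunc_5p < 0 or len(cons) - trunc_5p < 50:
        raise ValueError("truncation must leave at least 50 bp of the element")
    rng = np.random.default_rng(seed)
    element = cons[trunc_5p:]
    if divergence > 0:
        element = mutate_substitutions(rng, element, int(round(divergence / 100 * len(element))))
    tsd = ref[site:site + tsd_len]
    donor = ref[:site + tsd_len] + element + "A" * polyA_len + ref[site:]
    event = TASVEvent(
        event_id, "CLASSICAL_INS", contig, site, site,
        inserted_len=len(element) + polyA_len, tsd=tsd, polyA_len=polyA_len,
        trunc_start=trunc_5p, trunc_end=len(cons), subfamily1=subfamily,
    )
    return donor, event


def apply_ncai(genome: ReferenceGenome, contig: str, site: int, subfamily: str,
               trunc: tuple[int, int], target_del_len: int,
               library: ConsensusLibrary, seed: int = 0, divergence: float = 0.0,
               event_id: str = "ev") -> tuple[str, TASVEvent]:
    """Non-classical insertion: truncated element, no TSD, no poly-A, and deletion
    of ``target_del_len`` bp of pre-insertion reference sequence at the site."""
    ref = _check_site(genome, contig, site)
    if site + target_del_len > len(ref):
        raise ValueError("target deletion interval outside contig")
    c0, c1 = trunc
    cons = library[subfamily].sequence
    if not 0 <= c0 < c1 <= len(cons):
        raise ValueError("truncation interval outside consensus")
    rng = np.random.default_rng(seed)
    element = cons[c0:c1]
    if divergence > 0:
        element = mutate_substitutions(rng, element, int(round(divergence / 100 * len(element))))
    donor = ref[:site] + element + ref[site + target_del_len:]
    event = TASVEvent(
        event_id, "NCAI", contig, site, site + target_del_len,
        inserted_len=len(element), deleted_len=target_del_len,
        trunc_start=c0, trunc_end=c1, subfamily1=subfamily,
    )
    return donor, event


def _equivalent_position(ann: RepeatAnnotation, cons_pos: int) -> int:
    """Reference coordinate of a consensus position inside a +strand copy."""
    return ann.start + (cons_pos - ann.cons_start)


def apply_nahr_deletion(genome: ReferenceGenome, teA: RepeatAnnotation,
                        teB: RepeatAnnotation, crossover: int, homology_len: int,
                        library: ConsensusLibrary,
                        event_id: str = "ev") -> tuple[str, TASVEvent]:
    """Recombine two same-family + strand copies at ``crossover`` (consensus coords).

    The donor keeps teA's 5' part up to the crossover fused to teB's 3' part from
    the crossover — a single chimeric element. Requires >= homology_len identical
    bases starting at the crossover in both copies (engineer first if needed).
    """
    if teA.contig != teB.contig:
        raise ValueError("NAHR partners must lie on the same contig")
    if teA.strand != teB.strand or teA.strand != "+":
        raise ValueError("NAHR partners must share the + strand in this generator")
    famA = library.family_of(teA.subfamily)
    if famA != library.family_of(teB.subfamily):
        raise ValueError("NAHR partners must belong to the same family")
    if teA.start >= teB.start:
        raise ValueError("teA must be upstream of teB")
    for te in (teA, teB):
        if not te.cons_start <= crossover < te.cons_end:
            raise ValueError("crossover not contained in both copies")
    ref = genome.contigs[teA.contig]
    posA = _equivalent_position(teA, crossover)
    posB = _equivalent_position(teB, crossover)
    h = min(homology_len,
            min(teA.cons_end, teB.cons_end) - crossover)
    if ref[posA:posA + h] != ref[posB:posB + h]:
        raise ValueError(
            "insufficient identity at crossover: mutate the copies so the homology "
            "stretch exists before applying the event"
        )
    donor = ref[:posA] + ref[posB:]
    event = TASVEvent(
        event_id, "NAHR_DEL", teA.contig, posA, posB,
        deleted_len=posB - posA, homology_len=homology_len,
        subfamily1=teA.subfamily, subfamily2=teB.subfamily,
        cons_breakpoint=crossover,
    )
    return donor, event


def apply_nhej_deletion(genome: ReferenceGenome, contig: str, break5: int,
                        break3: int, microhomology_len: int, seed: int = 0,
                        event_id: str = "ev") -> tuple[str, TASVEvent]:
    """Join ``break5`` to ``break3`` (deleting [break5, break3)).

    Edits the *reference* context in place so that exactly ``microhomology_len``
    bases immediately upstream of both breakpoints are identical and the stretch
    cannot be extended on either side; the donor junction then carries exactly that
    engineered microhomology. At least one breakpoint must fall inside an
    annotated TE copy.
    """
    ref = _check_site(genome, contig, break5)
    if not break5 < break3 <= len(ref):
        raise ValueError("require break5 < break3 inside the contig")
    m = microhomology_len
    if m < 0 or m + 1 > break5 or break3 - m - 1 < 0:
        raise ValueError("microhomology window outside contig")
    in_te = any(a.contig == contig and (a.start <= break5 < a.end or a.start <= break3 < a.end)
                for a in genome.annotations)
    if not in_te:
        raise ValueError("neither breakpoint falls inside an annotated TE")

    rng = np.random.default_rng(seed)
    arr = np.frombuffer(ref.encode(), dtype="S1").copy()

    def force_diff(pos_keep: int, pos_edit: int) -> None:
        if arr[pos_edit] == arr[pos_keep]:
            alternatives = [b for b in b"ACGT" if bytes([b]) != arr[pos_keep]]
            arr[pos_edit] = bytes([alternatives[int(rng.integers(3))]])

    if m > 0:
        arr[break3 - m:break3] = arr[break5 - m:break5]
    force_diff(break5 - m - 1, break3 - m - 1)
    force_diff(break5, break3)  # no extension past the junction on the right
    new_ref = arr.tobytes().decode()
    genome.contigs[contig] = new_ref

    donor = new_ref[:break5] + new_ref[break3:]
    event = TASVEvent(
        event_id, "NHEJ_DEL", contig, break5, break3,
        deleted_len=break3 - break5, microhomology_len=m,
    )
    return donor, event


def apply_ltr_events(genome: ReferenceGenome, contig: str, variant: str,
                     site_or_copy, library: ConsensusLibrary, tsd_len: int = 8,
                     internal_keep: int = 30, seed: int = 0,
                     event_id: str = "ev") -> tuple[str, TASVEvent]:
    """LTR-retrotransposon variants.

    SOLITARY_LTR inserts one LTR block plus TSD at an empty site (int position).
    HERV_INTERNAL_DEL replaces a reference solitary-LTR copy (a RepeatAnnotation)
    with an LTR-(partial internal)-LTR structure.
    """
    herv = library["HERV-K"].sequence
    ltr = herv[:LTR_BLOCK_LEN]
    internal = herv[LTR_BLOCK_LEN:LTR_BLOCK_LEN + HERV_INTERNAL_LEN]
    if variant == "SOLITARY_LTR":
        if not isinstance(site_or_copy, (int, np.integer)):
            raise ValueError("SOLITARY_LTR requires an insertion site position")
        site = int(site_or_copy)
        ref = _check_site(genome, contig, site)
        tsd = ref[site:site + tsd_len]
        donor = ref[:site + tsd_len] + ltr + ref[site:]
        event = TASVEvent(
            event_id, "SOLITARY_LTR", contig, site, site,
            inserted_len=len(ltr), tsd=tsd,
            trunc_start=0, trunc_end=LTR_BLOCK_LEN, subfamily1="HERV-K",
        )
        return donor, event
    if variant == "HERV_INTERNAL_DEL":
        ann = site_or_copy
        if not isinstance(ann, RepeatAnnotation) or ann.subfamily != "HERV-K":
            raise ValueError("HERV_INTERNAL_DEL requires a solitary-LTR RepeatAnnotation")
        if (ann.cons_start, ann.cons_end) != (0, LTR_BLOCK_LEN):
            raise ValueError("reference copy is not a solitary LTR")
        ref = genome.contigs[ann.contig]
        keep = min(max(internal_keep, 0), HERV_INTERNAL_LEN)
        structure = ltr + internal[:keep] + ltr
        donor = ref[:ann.start] + structure + ref[ann.end:]
        event = TASVEvent(
            event_id, "HERV_INTERNAL_DEL", ann.contig, ann.start, ann.end,
            inserted_len=len(structure), deleted_len=len(ann),
            trunc_start=LTR_BLOCK_LEN + keep, trunc_end=LTR_BLOCK_LEN + HERV_INTERNAL_LEN,
            subfamily1="HERV-K",
        )
        return donor, event
    raise ValueError(f"unknown LTR variant {variant!r}")


# ---------------------------------------------------------------------------
# Whole-simulation orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Event counts scale the source study's confirmed catalog (182 insertions /
    89 deletions over six mechanisms) to a 200-event run; densities follow the
    observed genic Alu/L1 densities (14.91% / 11.81%); the Alu insertion size
    model is calibrated to a 292 bp mean; deletion sizes are mixtures placing
    ~75-80% of draws below 1 kb with support up to 14 kb.
    """

    n_contigs: int = 2
    contig_length: int = 1_500_000
    alu_density: float = 0.149
    l1_density: float = 0.118
    sva_density: float = 0.010
    ltr_density: float = 0.005
    gene_fraction: float = 0.40
    young_fraction: float = 0.15

    n_classical: int = 118
    n_ncai: int = 11
    n_solitary_ltr: int = 3
    n_herv_internal_del: int = 2
    n_nahr: int = 39
    n_nhej: int = 27
    n_nahr_l1: int = 2
    n_nhej_l1: int = 7

    flank_margin: int = 2300      # min clearance between events / from contig ends
    event_divergence: float = 0.0  # divergence of newly inserted elements

    def total_events(self) -> int:
        return (self.n_classical + self.n_ncai + self.n_solitary_ltr
                + self.n_herv_internal_del + self.n_nahr + self.n_nhej)

    def densities(self) -> dict[str, float]:
        return {"Alu": self.alu_density, "L1": self.l1_density,
                "SVA": self.sva_density, "LTR": self.ltr_density}


@dataclass
class SimulationResult:
    reference: ReferenceGenome
    donor: dict[str, str]
    events: list[TASVEvent]

    def truth_table(self) -> pd.DataFrame:
        return events_to_table(self.events)


# --- size / parameter models (the study conditions) -------------------------

def sample_tsd_len(rng) -> int:
    return int(rng.integers(5, 21))


def sample_polyA_len(rng) -> int:
    return int(rng.integers(8, 41))


def sample_alu_truncation(rng) -> int:
    """5' truncation of classical Alu insertions; 0 w.p. 0.6, else U(10,150)."""
    return 0 if rng.random() < 0.6 else int(rng.integers(10, 151))


def sample_nahr_homology(rng, max_h: int) -> int:
    """Log-normal, clipped to the observed 3-283 bp range (mean ~43 bp)."""
    h = int(round(rng.lognormal(math.log(30.0), 0.85)))
    return max(3, min(h, 283, max_h))


def sample_deletion_size(rng, mechanism: str, family: str) -> int:
    """Deletion-size mixtures: most draws <1 kb, support up to ~14 kb."""
    def logu(lo, hi):
        return int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    if mechanism == "NAHR_DEL":
        if family == "L1":
            return logu(1700, 14000)
        return logu(400, 1000) if rng.random() < 0.78 else logu(1000, 14000)
    if family == "L1":
        return logu(300, 1000) if rng.random() < 0.80 else logu(1000, 14000)
    return logu(200, 1000) if rng.random() < 0.80 else logu(1000, 14000)


def sample_microhomology(rng) -> int:
    return 0 if rng.random() < 0.35 else int(rng.integers(1, 19))


def sample_ncai_params(rng) -> tuple[tuple[int, int], int]:
    length = int(rng.integers(100, 291))
    c0 = int(rng.integers(0, 300 - length + 1))
    if rng.random() < 0.7:
        del_len = int(rng.integers(0, 51))
    else:
        del_len = int(math.exp(rng.uniform(math.log(50), math.log(3500))))
    return (c0, c0 + length), del_len


def _disambiguate_tsd_site(builder: _Builder, contig: str, site: int, tsd_len: int,
                           prev_chars: str, next_chars: str) -> None:
    """Make a planted TSD exactly as long as drawn.

    In the donor the left TSD copy is preceded by reference sequence and followed
    by the element; the right copy is preceded by the element tail (or poly-A)
    and followed by reference sequence. If reference bases around the target site
    echoed the bases around the right copy, the duplication would be extendable
    and the junction genuinely ambiguous; a 3 bp mismatch guard on each side
    keeps it identifiable even under a mismatch-tolerant detector.

    ``prev_chars``: donor bases immediately before the right TSD copy,
    nearest-first (poly-A tail or element tail). ``next_chars``: the element's
    first bases (what follows the left copy in the donor).
    """
    rng = builder.rng
    edits = [(site - 1 - i, c) for i, c in enumerate(prev_chars[:3])]
    edits += [(site + tsd_len + i, c) for i, c in enumerate(next_chars[:3])]
    for pos, forbidden in edits:
        if builder.base(contig, pos) == forbidden:
            choices = [b for b in "ACGT" if b != forbidden]
            builder.set_base(contig, pos, choices[int(rng.integers(3))])


def _tsd_extension_exists(left_frag: str, anchor1: int, right_frag: str,
                          anchor2: int, tsd_len: int, max_tsd: int = 30,
                          shift: int = 6) -> bool:
    """Whether the planted junction admits a duplication longer than the TSD.

    ``left_frag``/``right_frag`` are donor fragments around the two junctions,
    with ``anchor1`` the index just past the left TSD copy and ``anchor2`` the
    index of the right copy's first base. Periodic target sites or element heads
    can create exact duplications longer than the drawn TSD under small shifts,
    which would make the drawn TSD length unrecoverable by any detector.
    """
    for length in range(tsd_len + 1, max_tsd + 1):
        for a in range(-shift, shift + 1):
            lo = anchor1 - length + a
            if lo < 0 or anchor1 + a > len(left_frag):
                continue
            s = left_frag[lo: anchor1 + a]
            for b in range(-shift, shift + 1):
                if anchor2 + b < 0 or anchor2 + length + b > len(right_frag):
                    continue
                if right_frag[anchor2 + b: anchor2 + length + b] == s:
                    return True
    return False


_CLASSICAL_ALU_WEIGHTS = {
    # Table-2-shaped subfamily mix of confirmed classical Alu insertions
    "AluYa5": 0.50, "AluYb8": 0.24, "AluYb9": 0.07, "AluYc3": 0.05,
    "AluYa8": 0.05, "AluYh9": 0.04, "AluYg6": 0.02, "AluYd8": 0.01,
    "AluYk12": 0.01, "AluYk11": 0.01,
}


def simulate(config: SimulationConfig, seed: int,
             library: ConsensusLibrary | None = None) -> SimulationResult:
    """Build a reference and derive a donor genome by applying all configured events.

    Deterministic for a given (config, seed). Truth is reported in original
    reference coordinates; per-contig edits are applied right-to-left.
    """
    library = library or default_library()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    builder = _Builder(rng, config.n_contigs, config.contig_length, library)
    young_alu = [name for name in _CLASSICAL_ALU_WEIGHTS]
    margin = config.flank_margin

    # (mechanism, params) plan — drawn before any placement for determinism
    plan: list[dict] = []
    for i in range(config.n_classical):
        r = rng.random()
        if r < 0.965:
            sub = _weighted_choice(rng, _CLASSICAL_ALU_WEIGHTS)
            trunc = sample_alu_truncation(rng)
        elif r < 0.99:
            sub = "L1HS"
            trunc = 0 if rng.random() < 0.5 else int(rng.integers(500, 5501))
        else:
            sub = ["SVA_E", "SVA_F"][int(rng.integers(2))]
            trunc = 0 if rng.random() < 0.7 else int(rng.integers(100, 601))
        plan.append(dict(mech="CLASSICAL_INS", subfamily=sub, trunc=trunc,
                         tsd=sample_tsd_len(rng), polyA=sample_polyA_len(rng)))
    for i in range(config.n_ncai):
        trunc, del_len = sample_ncai_params(rng)
        plan.append(dict(mech="NCAI", subfamily=young_alu[int(rng.integers(len(young_alu)))],
                         trunc=trunc, del_len=del_len))
    for i in range(config.n_solitary_ltr):
        plan.append(dict(mech="SOLITARY_LTR", tsd=sample_tsd_len(rng)))
    for i in range(config.n_herv_internal_del):
        plan.append(dict(mech="HERV_INTERNAL_DEL", keep=int(rng.integers(10, 61))))
    for i in range(config.n_nahr):
        family = "L1" if i < config.n_nahr_l1 else "Alu"
        plan.append(dict(mech="NAHR_DEL", family=family,
                         size=sample_deletion_size(rng, "NAHR_DEL", family)))
    for i in range(config.n_nhej):
        family = "L1" if i < config.n_nhej_l1 else "Alu"
        plan.append(dict(mech="NHEJ_DEL", family=family,
                         size=sample_deletion_size(rng, "NHEJ_DEL", family),
                         mh=sample_microhomology(rng)))

    edits: dict[str, list[tuple[int, int, str, TASVEvent]]] = {n: [] for n in builder.names}
    herv = library["HERV-K"].sequence
    ltr_seq = herv[:LTR_BLOCK_LEN]
    internal = herv[LTR_BLOCK_LEN:LTR_BLOCK_LEN + HERV_INTERNAL_LEN]

    def choose_pair_subfamilies(family: str) -> tuple[str, str]:
        if family == "Alu":
            a = _weighted_choice(rng, _OLD_ALU_WEIGHTS)
            b = a if rng.random() < 0.6 else _weighted_choice(rng, _OLD_ALU_WEIGHTS)
        else:
            a = _weighted_choice(rng, _OLD_L1_WEIGHTS)
            b = a if rng.random() < 0.6 else _weighted_choice(rng, _OLD_L1_WEIGHTS)
        return a, b

    for idx, spec in enumerate(plan):
        mech = spec["mech"]
        ev_id = f"ev{idx:04d}"
        contig = builder.names[int(rng.integers(len(builder.names)))]
        res = builder.res[contig]

        if mech == "CLASSICAL_INS":
            site = res.try_place(rng, 1, pad=margin, margin=margin)
            if site is None:
                raise GenerationError("cannot place CLASSICAL_INS event")
            cons = library[spec["subfamily"]].sequence
            element = cons[spec["trunc"]:]
            if config.event_divergence > 0:
                element = mutate_substitutions(
                    rng, element, int(round(config.event_divergence / 100 * len(element))))
            t = spec["tsd"]
            arr = builder.arrays[contig]
            # keep the TSD unambiguous: the duplication must not be extendable —
            # the base before the target site must differ from the base preceding
            # the right TSD copy (the poly-A tail), and the base after it from the
            # element's first base
            _disambiguate_tsd_site(builder, contig, site, t, prev_chars="AAA",
                                   next_chars=element[:3])
            # a periodic target site or element head can admit a longer
            # duplication than the drawn TSD; rewrite the TSD tail until the
            # drawn length is the unique reading
            for _ in range(10):
                tsd = arr[site:site + t].tobytes().decode()
                ref_left = arr[site - 40:site].tobytes().decode()
                ref_right = arr[site + t:site + t + 20].tobytes().decode()
                tail = "A" * min(spec["polyA"], 20)
                if not _tsd_extension_exists(ref_left + tsd + element[:20],
                                             40 + t, tail + tsd + ref_right,
                                             len(tail), t):
                    break
                cur = builder.base(contig, site + t - 1)
                builder.set_base(contig, site + t - 1,
                                 [b for b in "ACGT" if b != cur][int(rng.integers(3))])
            tsd = arr[site:site + t].tobytes().decode()
            repl = tsd + element + "A" * spec["polyA"] + tsd
            ev = TASVEvent(ev_id, mech, contig, site, site,
                           inserted_len=len(element) + spec["polyA"], tsd=tsd,
                           polyA_len=spec["polyA"], trunc_start=spec["trunc"],
                           trunc_end=len(cons), subfamily1=spec["subfamily"])
            edits[contig].append((site, site + t, repl, ev))

        elif mech == "NCAI":
            (c0, c1), del_len = spec["trunc"], spec["del_len"]
            site = res.try_place(rng, max(del_len, 1), pad=margin, margin=margin)
            if site is None:
                raise GenerationError("cannot place NCAI event")
            element = library[spec["subfamily"]].sequence[c0:c1]
            ev = TASVEvent(ev_id, mech, contig, site, site + del_len,
                           inserted_len=len(element), deleted_len=del_len,
                           trunc_start=c0, trunc_end=c1, subfamily1=spec["subfamily"])
            edits[contig].append((site, site + del_len, element, ev))

        elif mech == "SOLITARY_LTR":
            site = res.try_place(rng, 1, pad=margin, margin=margin)
            if site is None:
                raise GenerationError("cannot place SOLITARY_LTR event")
            t = spec["tsd"]
            _disambiguate_tsd_site(builder, contig, site, t,
                                   prev_chars=ltr_seq[::-1], next_chars=ltr_seq[:3])
            arr = builder.arrays[contig]
            for _ in range(10):
                tsd = arr[site:site + t].tobytes().decode()
                ref_left = arr[site - 40:site].tobytes().decode()
                ref_right = arr[site + t:site + t + 20].tobytes().decode()
                if not _tsd_extension_exists(ref_left + tsd + ltr_seq[:20],
                                             40 + t, ltr_seq[-20:] + tsd + ref_right,
                                             20, t):
                    break
                cur = builder.base(contig, site + t - 1)
                builder.set_base(contig, site + t - 1,
                                 [b for b in "ACGT" if b != cur][int(rng.integers(3))])
            tsd = arr[site:site + t].tobytes().decode()
            repl = tsd + ltr_seq + tsd
            ev = TASVEvent(ev_id, mech, contig, site, site,
                           inserted_len=len(ltr_seq), tsd=tsd,
                           trunc_start=0, trunc_end=LTR_BLOCK_LEN, subfamily1="HERV-K")
            edits[contig].append((site, site + t, repl, ev))

        elif mech == "HERV_INTERNAL_DEL":
            # reference carries a solitary LTR; donor carries LTR-internal'-LTR
            start = res.try_place(rng, LTR_BLOCK_LEN, pad=margin, margin=margin)
            if start is None:
                raise GenerationError("cannot place HERV_INTERNAL_DEL event")
            ann = builder.plant(contig, start, "HERV-K", 0, LTR_BLOCK_LEN,
                                float(rng.uniform(1.0, 4.0)), "+")
            keep = spec["keep"]
            structure = ltr_seq + internal[:keep] + ltr_seq
            ev = TASVEvent(ev_id, mech, contig, ann.start, ann.end,
                           inserted_len=len(structure), deleted_len=len(ann),
                           trunc_start=LTR_BLOCK_LEN + keep,
                           trunc_end=LTR_BLOCK_LEN + HERV_INTERNAL_LEN,
                           subfamily1="HERV-K")
            edits[contig].append((ann.start, ann.end, structure, ev))

        elif mech == "NAHR_DEL":
            family = spec["family"]
            size = spec["size"]
            subA, subB = choose_pair_subfamilies(family)
            if family == "Alu":
                c_lo, c_hi = 0, 300
            else:
                c_lo, c_hi = 2000, 3500
            clen = c_hi - c_lo
            if size < clen + 30:
                size = clen + 30 + int(rng.integers(0, 50))
            h = sample_nahr_homology(rng, max_h=clen - 60)
            crossover = int(rng.integers(c_lo + 25, c_hi - h - 25))
            span = size + clen
            start = res.try_place(rng, span, pad=margin, margin=margin)
            if start is None:
                raise GenerationError("cannot place NAHR_DEL event")
            divA = float(rng.uniform(4.0, 12.0))
            divB = float(rng.uniform(4.0, 12.0))
            teA = builder.plant(contig, start, subA, c_lo, c_hi, divA, "+")
            teB = builder.plant(contig, start + size, subB, c_lo, c_hi, divB, "+")
            # engineer the homology stretch: identical on [crossover, crossover+h),
            # mismatching immediately on both sides
            consA = library[subA].sequence
            arr = builder.arrays[contig]
            for te in (teA, teB):
                off = te.start - c_lo
                window = consA[crossover:crossover + h]
                arr[off + crossover:off + crossover + h] = np.frombuffer(
                    window.encode(), dtype="S1")
            pA = teA.start - c_lo
            pB = teB.start - c_lo
            builder.force_mismatch(contig, pA + crossover - 1, pB + crossover - 1)
            builder.force_mismatch(contig, pA + crossover + h, pB + crossover + h)
            posA = _equivalent_position(teA, crossover)
            posB = _equivalent_position(teB, crossover)
            ev = TASVEvent(ev_id, mech, contig, posA, posB,
                           deleted_len=posB - posA, homology_len=h,
                           subfamily1=subA, subfamily2=subB, cons_breakpoint=crossover)
            edits[contig].append((posA, posB, "", ev))

        elif mech == "NHEJ_DEL":
            family = spec["family"]
            size = spec["size"]
            m = spec["mh"]
            subA, subB = choose_pair_subfamilies(family)
            if family == "Alu":
                c_lo, c_hi = 0, 300
            else:
                c_lo, c_hi = 2000, 3500
            clen = c_hi - c_lo
            # breakpoint offsets into each copy; keep >= 80 bp of the 5' remnant and
            # >= 25 bp of consensus-position separation so NHEJ junctions are never
            # confusable with a contiguous NAHR chimera; copies must not overlap
            offA = offB = -1
            for _ in range(400):
                offB = int(rng.integers(80, clen - 25))
                lowA = max(80, offB + clen + 30 - size)
                if lowA > clen - 26:
                    continue
                offA = int(rng.integers(lowA, clen - 25))
                if abs(offA - offB) >= 25:
                    break
            else:
                raise GenerationError("cannot draw NHEJ breakpoint offsets for size "
                                      f"{size} in a {clen} bp copy")
            span = offA + size - offB + clen
            start = res.try_place(rng, span, pad=margin, margin=margin)
            if start is None:
                raise GenerationError("cannot place NHEJ_DEL event")
            d5 = start + offA
            d3 = d5 + size
            teA = builder.plant(contig, start, subA, c_lo, c_hi,
                                float(rng.uniform(4.0, 12.0)), "+")
            builder.plant(contig, d3 - offB, subB, c_lo, c_hi,
                          float(rng.uniform(4.0, 12.0)), "+")
            arr = builder.arrays[contig]
            if m > 0:
                arr[d3 - m:d3] = arr[d5 - m:d5]
            builder.force_mismatch(contig, d5 - m - 1, d3 - m - 1)
            builder.force_mismatch(contig, d5, d3)
            ev = TASVEvent(ev_id, mech, contig, d5, d3,
                           deleted_len=size, microhomology_len=m,
                           subfamily1=subA, subfamily2=subB)
            edits[contig].append((d5, d3, "", ev))

        else:  # pragma: no cover
            raise GenerationError(f"unknown mechanism {mech}")

    _plant_background(builder, config.densities(), config.young_fraction)
    _plan_genes(builder, config.gene_fraction)
    reference = builder.freeze()

    donor: dict[str, str] = {}
    events: list[TASVEvent] = []
    for contig in builder.names:
        seq = reference.contigs[contig]
        for s, e, repl, ev in sorted(edits[contig], key=lambda t: -t[0]):
            seq = seq[:s] + repl + seq[e:]
        donor[contig] = seq
        events.extend(ev for _, _, _, ev in sorted(edits[contig], key=lambda t: t[0]))

    result = SimulationResult(reference, donor, events)
    # conservation sanity check: signed truth bookkeeping must explain every contig
    for contig in builder.names:
        expected = sum(ev.net_change for ev in events if ev.contig == contig)
        actual = len(donor[contig]) - len(reference.contigs[contig])
        if expected != actual:  # pragma: no cover - internal consistency guard
            raise GenerationError(
                f"bookkeeping violation on {contig}: truth {expected} vs measured {actual}")
    return result


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write reference/donor FASTA, the truth table and BED tracks to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "donor": outdir / "donor.fa",
        "truth": outdir / "truth.tsv",
        "repeats": outdir / "repeats.bed",
        "genes": outdir / "genes.bed",
    }
    write_fasta(paths["reference"], result.reference.contigs)
    write_fasta(paths["donor"], result.donor)
    result.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    write_bed(paths["repeats"], (
        BedRecord(a.contig, a.start, a.end, a.subfamily,
                  str(int(round(a.divergence * 10))), a.strand)
        for a in result.reference.annotations))
    write_bed(paths["genes"], (
        BedRecord(g.contig, g.start, g.end, f"{g.gene}:{g.feature}", "0", ".")
        for g in result.reference.genes))
    return paths
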