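"""End-to-end orchestration: annotate -> mine -> classify -> report.

The stages are the spec'd operations; this module adds the routing glue:

* candidates whose reference gap holds a matching copy of the same element are
  concordant (shared by both genomes) and dropped;
* deletion-shaped candidates whose donor element turns out to be a novel
  young-subfamily insertion (the junction does not continue the reference) are
  re-routed to insertion classification — that is how target-deleting NCAIs
  larger than the adjacency gap are recovered;
* near-identical deletion junctions discovered from both partner remnants are
  de-duplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import AnnotationHit, hits_to_bed, hits_to_table, scan
from .classify import (JunctionCall, analyze_insertion_candidate, calls_to_table,
                       classify_deletion)
from .genome import GeneFeature
from .io import (PipelineConfig, RunManifest, file_checksum, read_bed, read_fasta,
                 write_bed, write_tsv_table, config_to_text)
from .library import ConsensusLibrary, default_library, load_library, young_subfamilies
from .mining import (CandidateLocus, ReferenceIndex, call_candidates,
                     dedupe_deletion_candidates, extract_loci, filter_concordant,
                     loci_to_table, place_flanks, require_deletion_flank_repeats)
from .report import calls_to_accounting, summarize

log = logging.getLogger("tasvkit")


@dataclass
class PipelineResult:
    ref_hits: list[AnnotationHit]
    donor_hits: list[AnnotationHit]
    loci: list[CandidateLocus]
    calls: list[JunctionCall]
    counts: dict = field(default_factory=dict)

    def calls_table(self) -> pd.DataFrame:
        return calls_to_table(self.calls)


def _subtract_known_sites(loci: list[CandidateLocus], known_sites, tol: int = 100):
    for locus in loci:
        if locus.kind not in ("INSERTION_CANDIDATE", "DELETION_CANDIDATE"):
            continue
        lp, rp = locus.left_placement, locus.right_placement
        for site in known_sites:
            if (site.contig == lp.contig and site.start < rp.start + tol
                    and site.end > lp.end - tol):
                locus.kind, locus.reason = "REJECTED", "previously reported"
                break
    return loci


def _dedupe_deletions(calls: list[JunctionCall], tol: int = 25) -> list[JunctionCall]:
    kept: list[JunctionCall] = []
    out: list[JunctionCall] = []
    for call in calls:
        if not call.mechanism.endswith("_DEL"):
            out.append(call)
            continue
        dup = next((k for k in kept if k.contig == call.contig
                    and abs(k.ref_start - call.ref_start) <= tol
                    and abs(k.ref_end - call.ref_end) <= tol), None)
        if dup is None:
            kept.append(call)
            out.append(call)
        else:
            dup.notes.append(f"junction also recovered from locus {call.locus_id}")
    return out


def run_calls(reference: dict[str, str], donor: dict[str, str],
              library: ConsensusLibrary, config: PipelineConfig,
              known_sites=None) -> PipelineResult:
    """Run annotate -> mine -> classify on in-memory genomes."""
    config.validate()
    young = young_subfamilies(library)

    log.info("annotating reference and donor")
    scan_kw = dict(min_len=config.min_hit_len, max_divergence=config.max_divergence,
                   k=config.annotator_k, band=config.annotator_band)
    ref_hits = scan(reference, library, **scan_kw)
    donor_hits = scan(donor, library, **scan_kw)

    log.info("extracting loci and placing flanks")
    loci = extract_loci(donor_hits, donor, set(library.names), config.flank_len)
    for locus in loci:
        locus.family = library.family_of(locus.subfamily)
    ref_index = ReferenceIndex(reference)
    for locus in loci:
        place_flanks(locus, ref_index, config.placement_min_identity,
                     config.placement_ambiguity_margin)
    call_candidates(loci, config.min_insertion_len, config.adjacency_gap)
    filter_concordant(loci, ref_hits, library)
    dedupe_deletion_candidates(loci)
    if known_sites:
        _subtract_known_sites(loci, known_sites)

    log.info("classifying junctions")
    calls: list[JunctionCall] = []
    for locus in loci:
        if locus.kind == "INSERTION_CANDIDATE":
            if locus.subfamily in young:
                calls.append(analyze_insertion_candidate(
                    locus, donor, library, max_tsd=config.max_tsd,
                    ltr_block_len=config.ltr_block_len, reference=reference))
            else:
                locus.kind, locus.reason = "REJECTED", "not a young-subfamily element"
        elif locus.kind == "DELETION_CANDIDATE":
            if locus.family == "LTR" and locus.subfamily in young:
                # a deletion-shaped LTR locus (reference gap = solitary LTR) is an
                # LTR structural variant; try the insertion block rules first
                call = analyze_insertion_candidate(
                    locus, donor, library, max_tsd=config.max_tsd,
                    ltr_block_len=config.ltr_block_len, reference=reference)
                if call.mechanism in ("SOLITARY_LTR", "HERV_INTERNAL_DEL"):
                    calls.append(call)
                    continue
            keep, _track = require_deletion_flank_repeats(
                locus, ref_hits, library, config.flank_len)
            call = None
            if keep:
                call = classify_deletion(locus, ref_hits, reference, donor, library,
                                         min_homology=config.min_homology)
            novel = (call is None or (call.mechanism == "UNCLASSIFIED"
                                      and any("novel_element" in n for n in call.notes)))
            if novel and locus.subfamily in young:
                calls.append(analyze_insertion_candidate(
                    locus, donor, library, max_tsd=config.max_tsd,
                    ltr_block_len=config.ltr_block_len, reference=reference))
            elif call is not None:
                calls.append(call)
            else:
                locus.kind, locus.reason = ("REJECTED",
                                            "no same-family repeats in both flanks")
    calls = _dedupe_deletions(calls)

    counts = {
        "ref_annotations": len(ref_hits),
        "donor_annotations": len(donor_hits),
        "loci": len(loci),
        "insertion_candidates": sum(l.kind == "INSERTION_CANDIDATE" for l in loci),
        "deletion_candidates": sum(l.kind == "DELETION_CANDIDATE" for l in loci),
        "rejected": sum(l.kind == "REJECTED" for l in loci),
        "calls": len(calls),
    }
    for call in calls:
        counts[f"calls_{call.mechanism}"] = counts.get(f"calls_{call.mechanism}", 0) + 1
    return PipelineResult(ref_hits, donor_hits, loci, calls, counts)


def read_gene_model(path) -> list[GeneFeature]:
    """Gene model BED: the name column is gene:feature (feature = UTR5/exon/intron/UTR3)."""
    feats = []
    for rec in read_bed(path):
        gene, _, feature = rec.name.partition(":")
        feats.append(GeneFeature(rec.contig, rec.start, rec.end, gene,
                                 feature or "exon"))
    return feats


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """File-level pipeline: read inputs per config, run all stages, write artifacts.

    Writes annotation tables/BED, the candidate table with rejection reasons, the
    classified call table, the summary table, the effective config, and a JSON
    manifest with per-stage record counts and input checksums.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.txt").write_text(config_to_text(config))

    library = load_library(config.library) if config.library else default_library()
    reference = read_fasta(config.reference)
    donor = read_fasta(config.donor)
    known = read_bed(config.known_sites) if config.known_sites else None

    manifest = RunManifest(version=__version__, seed=config.seed)
    for key in ("library", "reference", "donor", "gene_model", "known_sites"):
        path = getattr(config, key)
        if path:
            manifest.inputs[key] = {"path": str(path), "sha256": file_checksum(path)}

    result = run_calls(reference, donor, library, config, known_sites=known)

    write_tsv_table(outdir / "reference_annotations.tsv", hits_to_table(result.ref_hits))
    write_tsv_table(outdir / "donor_annotations.tsv", hits_to_table(result.donor_hits))
    write_bed(outdir / "reference_annotations.bed", hits_to_bed(result.ref_hits))
    write_tsv_table(outdir / "candidates.tsv", loci_to_table(result.loci))
    write_tsv_table(outdir / "calls.tsv", result.calls_table())
    write_tsv_table(outdir / "summary.tsv", summarize(result.calls))

    if config.gene_model:
        from .report import genic_overlap
        genes = read_gene_model(config.gene_model)
        labels, counts = genic_overlap(calls_to_accounting(result.calls), genes)
        table = result.calls_table()
        table["genic_feature"] = labels.values
        write_tsv_table(outdir / "calls.tsv", table)
        result.counts["genic_labels"] = counts.to_dict()

    manifest.stage_counts = result.counts
    manifest.write(outdir / "manifest.json")
    return manifest
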