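# Methods

## Scope and model

`tasvkit` treats a TASV (transposable-element-associated structural variant) as a
difference between a donor (personal, de novo-assembled) genome and a reference
genome whose creation involved a TE. Six mechanisms are modeled, matching the
classes observed in comparative studies of assembled human genomes: classical
retrotransposon insertion, non-classical Alu insertion (NCAI), solitary-LTR
insertion, HERV insertion with internal deletion, NAHR deletion (recombination
between two same-family copies) and NHEJ deletion (TE-anchored end joining).

The method assumes assembled sequence on both sides — no reads, no alignment
uncertainty beyond sequence divergence. Assembly itself (and the wet-lab
validation such a study would perform) is out of scope; the pipeline starts from
two FASTA files and a repeat-consensus library.

## Pipeline

1. **Repeat annotation** (`annotate.scan`). Exact k-mer anchors (default k = 13)
   between genome and consensus, both strands, are grouped by alignment diagonal
   (band 16) and genome-position gaps (≤ 350 bp), extended with a greedy x-drop
   (match +1, mismatch −2, drop 12), and scored by a global edit-distance
   alignment (edlib). Divergence = (mismatches + indels) / alignment length, in
   percent. Overlapping hits from related consensi resolve to the higher score
   with deterministic ties (library order). Low-complexity segments (one base
   ≥ 85%) are discarded — a stand-in for tandem-repeat masking, adequate because
   the simulator plants no tandem arrays. Diagonal chaining assumes copies
   diverge mostly by substitutions; heavily indel-rearranged copies fragment
   into multiple hits.

2. **Locus extraction and flank placement** (`mining`). Every donor copy of the
   requested subfamilies becomes a candidate locus with up to `flank_len`
   (default 2000 bp, valid 500–4000) of flanking sequence per side; adjacent
   same-subfamily hits (gap ≤ 5 bp) merge, so structured elements
   (LTR–internal–LTR) and junction-split copies surface as one locus. Insertion
   discovery uses the young subfamilies; deletion discovery needs the whole
   library, because recombination partners are mostly older subfamilies. Flanks
   place on the reference via an exact 32-mer anchor near the outer flank end
   plus gapless x-drop extension toward the element — donor flanks are nearly
   verbatim reference sequence, so this pins the inner breakpoint exactly; a
   banded edlib search over every contig is the fallback. Placements need
   ≥ 95% identity; a flank with two placements within 2% identity of each other
   is rejected as ambiguous rather than guessed, and flanks under 200 usable bp
   are rejected outright.

3. **Candidate calling and filters**. Placements adjacent or overlapping in the
   reference (gap ≤ 50 bp) with a donor element ≥ 100 bp yield insertion
   candidates (the < 100 bp filter mirrors the mining protocol this pipeline
   algorithmizes); co-linear placements with a larger gap yield deletion
   candidates, with no size selection. Loci containing ≥ 5 consecutive N are
   dropped as ambiguous sequence. Three additional filters keep the candidate
   set honest: a *concordance* filter drops loci whose reference gap holds a
   same-family annotation of matching length (a copy shared by both genomes, not
   a variant); near-identical deletion junctions mined from both partner
   remnants are de-duplicated (the locus with the longer donor element wins);
   and an optional BED of known polymorphic sites is subtracted. The 50 bp
   adjacency threshold exceeds the maximum TSD length (30) plus placement
   jitter, so no classical insertion is ever mistaken for a deletion.

4. **Junction classification** (`classify`). Insertions: the poly-A tail is
   located as the maximal pure-A run at the element 3' end (the permissive
   ≥ 80%-adenine rule of `detect_polyA`, applied to an open window, would
   swallow A-rich target sequence); the TSD is the longest duplication
   (5–30 bp, ≤ 10% internal mismatches, matching endpoints) across the two
   junctions, with small window offsets absorbing annotation jitter; a TSD is
   accepted only when the flank placements also overlap in the reference — the
   physical signature of a duplicated target. Decision order: solitary LTR
   block → SOLITARY_LTR; both LTR blocks with a partially absent internal
   segment → HERV_INTERNAL_DEL; TSD present → CLASSICAL_INS; no TSD and
   (no poly-A or truncated) → NCAI with the reference gap as the
   pre-insertion deletion; otherwise UNCLASSIFIED (kept as a first-class
   outcome, never forced). Deletions: exact common extension from both flank
   placements pins the junction; the shared stretch between the two extensions
   is the junction ambiguity `s`. If the upstream and downstream partner copies
   meet at equivalent consensus positions (|Δ| ≤ 3) with `s` ≥ 3 bp — the
   observed minimum homology — the call is NAHR with homology `s` and the
   crossover reported as the consensus interval of the shared stretch (a point
   inside a perfect-identity stretch is unidentifiable, so tallies use interval
   midpoints); otherwise NHEJ with the microhomology measured by
   `measure_microhomology`. A deletion-shaped candidate whose donor element
   does not continue the reference at either breakpoint is a novel insertion
   and is re-routed to the insertion rules — this is how NCAIs with target
   deletions larger than the adjacency gap are recovered.

5. **Accounting** (`report`). bp gained counts inserted sequence plus one extra
   TSD copy for the TSD-generating mechanisms; bp lost counts deleted reference
   sequence; NCAI rows carry both. The summary's total net change equals the
   signed sum of per-call contributions, which in turn equals the measured
   donor-minus-reference length difference on simulated data. Callset
   comparison greedily matches loci one-to-one by increasing distance (default
   tolerance 100 bp, deterministic tie-breaks) and reports signed per-pair
   errors; per-gene TE density uses the interval union of family copies so
   overlap never inflates a density past 1.

### Breakpoint conventions

NHEJ deletions are reported right-aligned: break5 is the last base that must
derive from the upstream side, and the microhomology S then simultaneously ends
the reference context upstream of break5 and begins the context downstream of
break3, appearing exactly once at the donor junction. NAHR deletions are
left-aligned at the start of the homology stretch. Both conventions make the
called interval coincide with the simulator's truth coordinates.

## The simulator

The generator's defaults are the study conditions the pipeline is validated
under: a two-contig, 3 Mb reference with planted TE densities Alu 14.9%,
L1 11.8% (the observed genic densities), SVA 1%, LTR 0.5%; gene models (UTR5 /
exon / intron / UTR3) covering ~40% of the sequence; and 200 events mixing
118 classical insertions (Alu : L1 : SVA weighted ~155 : 4 : 2, AluYa5 and
AluYb8 dominant), 11 NCAIs, 3 solitary LTRs, 2 HERV internal deletions,
39 NAHR deletions (2 on L1) and 27 NHEJ deletions (7 on L1) — the confirmed
catalog of the motivating study scaled to 200. Old-subfamily copies carry
5–20% divergence, young copies 0.5–3%; newly inserted elements are divergence-0
by default (`event_divergence` raises this). All randomness flows from one
integer seed; identical (config, seed) gives byte-identical outputs.

Size and hallmark models, with the reasoning:

* **TSD** uniform 5–20 bp (typical L1-endonuclease target duplications);
  **poly-A** uniform 8–40 adenines for classical insertions, absent for NCAIs.
* **Alu insertion size**: 5' truncation 0 with probability 0.6, else
  U(10, 150); with the poly-A tail this makes mean inserted length ≈ 292 bp,
  the observed average. L1 insertions are 5'-truncated half the time
  (truncation point uniform — a modeling choice, config-exposed); the
  truncation always leaves ≥ 50 bp of element.
* **Deletion sizes** are per-mechanism log-uniform mixtures calibrated so
  ~75% of draws fall below 1 kb with support up to 14 kb. Alu NAHR sizes start
  at 400 bp because two non-overlapping full-length 300 bp partners bound the
  deletion from below; NHEJ sizes reach down to 200 bp.
* **NAHR homology**: log-normal (median 30 bp, σ = 0.85), clipped to the
  observed 3–283 bp range (mean ≈ 43 bp). The window is engineered: both
  partner copies are rewritten to the consensus over [crossover,
  crossover + h) and forced to mismatch immediately on both sides, so the
  maximal shared identical stretch is exactly h.
* **Microhomology**: 0 with probability 0.35, else uniform 1–18 bp, engineered
  the same way (identical bases immediately upstream of both breakpoints,
  mismatches at both boundaries). Breakpoint consensus positions are kept
  ≥ 25 apart so an NHEJ junction can never masquerade as a contiguous chimera.
* **Junction identifiability**: around every planted TSD the simulator forces a
  3 bp mismatch guard against the poly-A tail and the element head, and
  rewrites the TSD tail if a periodic target site would admit a longer
  duplication reading. Without this, a detector — or a human inspector — could
  not recover the drawn TSD, because the sequence genuinely admits another
  interpretation.

Events never overlap each other or planted copies (interval bookkeeping with
bounded rejection sampling; exhaustion raises a generation error naming the
mechanism) and keep ≥ 2.3 kb of clearance so flanks stay clean. Edits apply
right-to-left per contig; truth is always in original reference coordinates.

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: sequencing and assembly error, heterozygosity and
diploidy, nested or overlapping events, inverted (twin-priming) insertions,
tandem repeat arrays, indel divergence within planted copies (substitutions
only), transduced sequence, and the biased genomic distribution of real TEs.
Real consensus libraries are longer and internally repetitive (SVA VNTRs, L1
A-rich stretches) in ways the synthetic library is not. Recovery rates near 1.0
on this simulator demonstrate correctness of the junction logic and
bookkeeping, not expected performance on a real assembly.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `flank_len` | 2000 bp | donor flank extracted per side (500–4000 accepted) |
| `min_insertion_len` | 100 bp | insertion candidates below this are filtered out |
| `adjacency_gap` | 50 bp | reference gap at/below which placements are "adjacent" |
| `max_tsd` / `min_tsd` | 30 / 5 bp | TSD search range; the 5 bp floor avoids chance duplications at toy scale |
| `tsd_max_mismatch_frac` | 0.10 | internal mismatches tolerated in the TSD copy |
| `min_homology` | 3 bp | NAHR floor (observed minimum homology stretch) |
| `placement_min_identity` | 0.95 | flank placement acceptance |
| `placement_ambiguity_margin` | 0.02 | two placements closer than this in identity → ambiguous |
| `annotator_k` / `annotator_band` | 13 / 16 | anchor length and diagonal tolerance |
| `max_divergence` | 25% | annotation divergence cap |
| `match_tolerance` | 100 bp | callset comparison matching distance |
| `ltr_block_len` | 450 bp | LTR block length for solitary/internal-deletion structure calls |

Annotator parameters are config-exposed rather than fixed because the
sensitivity settings of production repeat maskers vary; the defaults are tuned
for the bundled library's element lengths.

## Numerical and degenerate-input choices

* Ambiguity codes in consensus input are rejected, not masked, to keep the
  divergence arithmetic well defined; N-stretches in candidate loci drop the
  locus with a recorded reason.
* TSD ties break longest → fewest mismatches → smallest window offsets; the
  copy's endpoints must match exactly, because tolerating a mismatched end base
  would systematically overcall length by one under the longest-first rule.
* `detect_polyA` follows the ≥ 80%-adenine, ≥ 6 bp, ends-on-A rule; the
  pipeline bounds its window by the pure-A run first (see above).
* A TSD string without placement overlap (≥ 3 bp) is ignored — a chance
  duplication, not a target-site signature.
* Identical NAHR partners make the crossover unresolvable; the crossover
  interval is then the full shared consensus span and the call is flagged.
* UNCLASSIFIED is retained rather than forced into a mechanism; downstream
  accounting carries it as its own class.
* All tables round-trip losslessly through TSV (`.` encodes empty fields);
  FASTA wraps at 60 columns; CRLF input is normalized.

## Known limitations

* Flank placement supports forward-strand donor scaffolds; an inverted scaffold
  should be reverse-complemented upstream (assembly orientation is outside this
  package's scope).
* NAHR analysis assumes + strand partner copies and substitution-dominated
  divergence (consensus coordinates are mapped by offset, not realignment).
* The annotator is a desk-scale stand-in: no Repbase taxonomy, no scoring
  matrices, no tandem-repeat finder. On multi-megabase genomes it is fast
  enough (seconds per Mb), but it is not a production repeat masker.
* `compare_callsets` is O(n·m) per contig pair; adequate for hundreds of loci,
  not for genome-wide SV databases.
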