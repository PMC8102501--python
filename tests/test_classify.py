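import numpy as np
import pytest

import tasvkit as tk
from brute import brute_microhomology, brute_tsd
from tasvkit.classify import (crossover_tally, detect_polyA,
                              detect_tsd, map_crossover_to_consensus,
                              measure_microhomology)
from tasvkit.genome import (ReferenceGenome, RepeatAnnotation, apply_nahr_deletion,
                            apply_ncai, apply_nhej_deletion)
from tasvkit.io import PipelineConfig
from tasvkit.sequtil import mutate_substitutions, random_seq

BASES = np.frombuffer(b"ACGT", dtype="S1")


def rand(rng, n):
    return random_seq(rng, n)


class TestDetectTsd:
    def test_constructed_identity(self):
        tsd = "ACGTACGTACGT"
        call = detect_tsd("TTTTTGGGCC" + tsd, tsd + "GGCCCTTAAA")
        assert call.seq == tsd and call.mismatches == 0

    def test_random_windows_no_call(self, rng):
        hits = sum(detect_tsd(rand(rng, 40), rand(rng, 40)) is not None
                   for _ in range(50))
        assert hits <= 2  # chance 5-mers are rare but possible

    def test_windows_too_short(self):
        assert detect_tsd("ACG", "ACG") is None

    def test_longest_wins_then_fewest_mismatches(self):
        left = "CCCCCCGGATTACA"
        right = "GGATTACACCCCCC"
        call = detect_tsd(left, right)
        assert call.seq == "GGATTACA"

    def test_brute_force_equivalence_500_junctions(self):
        rng = np.random.default_rng(424242)
        agree = 0
        for i in range(500):
            # half the junctions carry a planted duplication, half are random
            if i % 2 == 0:
                tsd = rand(rng, int(rng.integers(5, 25)))
                left = rand(rng, 30) + tsd
                right = tsd + rand(rng, 30)
            else:
                left, right = rand(rng, 45), rand(rng, 45)
            lo, ro = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            got = detect_tsd(left, right, max_left_offset=lo, max_right_offset=ro)
            expected = brute_tsd(left, right, max_left_offset=lo, max_right_offset=ro)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.seq, got.mismatches) == expected
            agree += 1
        assert agree == 500


class TestDetectPolyA:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAAAAAA", 10),
        ("ACGTACGTAC", 0),
        ("AAAAAAAATA", 10),   # 9/10 adenine passes the 80% rule
        ("AAAAA", 0),         # below the 6 bp floor
        ("AAAAAATTTT", 6),
    ])
    def test_rule_arithmetic(self, seq, expected):
        assert detect_polyA(seq) == expected

    def test_window_floor(self):
        with pytest.raises(ValueError):
            detect_polyA("AAAAAAAAAAAA", window=5)


class TestMeasureMicrohomology:
    def test_constructed_seven(self, rng):
        s = "GATTACA"
        ctx5 = rand(rng, 20) + s
        ctx3 = s + rand(rng, 20)
        junction = ctx5[-15:] + ctx3[7:22]  # S appears once, at the boundary
        assert measure_microhomology(junction, ctx5, ctx3, max_mh=15) == 7

    def test_no_shared_bases(self):
        assert measure_microhomology("C" * 20 + "G" * 20, "C" * 20, "G" * 20) == 0

    def test_brute_force_equivalence_500_junctions(self):
        rng = np.random.default_rng(77)
        for i in range(500):
            m = int(rng.integers(0, 19))
            s = rand(rng, m)
            ctx5 = rand(rng, 25) + s
            ctx3 = s + rand(rng, 25)
            k = 20
            junction = ctx5[-k:] + ctx3[m:m + k]
            got = measure_microhomology(junction, ctx5, ctx3, max_mh=k)
            assert got == brute_microhomology(junction, ctx5, ctx3, max_mh=k)


class TestMapCrossover:
    def test_engineered_crossover_interval(self, rng, library):
        cons = library["AluSx"].sequence
        up = list(mutate_substitutions(rng, cons, 25))
        down = list(mutate_substitutions(rng, cons, 25))
        c0, h = 150, 20
        window = cons[c0:c0 + h]
        up[c0:c0 + h] = window
        down[c0:c0 + h] = window
        if up[c0 - 1] == down[c0 - 1]:
            down[c0 - 1] = next(b for b in "ACGT" if b != up[c0 - 1])
        if up[c0 + h] == down[c0 + h]:
            down[c0 + h] = next(b for b in "ACGT" if b != up[c0 + h])
        up, down = "".join(up), "".join(down)
        chimera = up[:c0] + down[c0:]
        lo, hi, flagged = map_crossover_to_consensus(
            chimera, (0, 300), up, 0, down, 0)
        assert not flagged
        assert lo <= 150 < hi and hi - lo == 20

    def test_identical_copies_flagged_unresolvable(self, library):
        cons = library["AluSx"].sequence
        lo, hi, flagged = map_crossover_to_consensus(cons, (0, 300), cons, 0, cons, 0)
        assert flagged and (lo, hi) == (0, 300)

    def test_tally_recovers_spiked_mode(self, rng):
        intervals = []
        for _ in range(60):  # spike within the bin starting at consensus 150
            c = 150 + int(rng.integers(0, 5))
            intervals.append((c - 10, c + 10))
        for _ in range(30):  # uniform background
            c = int(rng.integers(20, 280))
            intervals.append((c - 10, c + 10))
        tally = crossover_tally(intervals, consensus_len=300, bin_width=10)
        assert tally.idxmax() == 150
        assert tally.sum() == 90


def two_copy_genome(rng, library, sub, spacing, cons_interval=(0, 300),
                    homology=None, crossover=None, n_subs=24):
    """Reference with two diverged same-subfamily copies; optional engineered
    identity window [crossover, crossover+homology) bounded by mismatches."""
    c0, c1 = cons_interval
    cons = library[sub].sequence
    copyA = list(mutate_substitutions(rng, cons[c0:c1], n_subs))
    copyB = list(mutate_substitutions(rng, cons[c0:c1], n_subs))
    if homology is not None:
        w0 = crossover - c0
        copyA[w0:w0 + homology] = cons[crossover:crossover + homology]
        copyB[w0:w0 + homology] = cons[crossover:crossover + homology]
        for edge in (w0 - 1, w0 + homology):
            if copyA[edge] == copyB[edge]:
                copyB[edge] = next(b for b in "ACGT" if b != copyA[edge])
    posA = 10_000
    posB = posA + spacing
    seq = random_seq(rng, 2 * posA + spacing + (c1 - c0))
    seq = seq[:posA] + "".join(copyA) + seq[posA + (c1 - c0):]
    seq = seq[:posB] + "".join(copyB) + seq[posB + (c1 - c0):]
    annA = RepeatAnnotation("chr1", posA, posA + (c1 - c0), "+", sub, c0, c1, 8.0)
    annB = RepeatAnnotation("chr1", posB, posB + (c1 - c0), "+", sub, c0, c1, 8.0)
    return ReferenceGenome({"chr1": seq}, [annA, annB]), annA, annB


class TestDeletionClassification:
    def run_one(self, genome, donor, library):
        result = tk.run_calls(genome.contigs, {"chr1": donor}, library,
                              PipelineConfig())
        dels = [c for c in result.calls if c.mechanism.endswith("_DEL")]
        assert len(dels) == 1
        return dels[0]

    def test_nahr_with_average_homology(self, library):
        """Engineered 43 bp homology stretch is measured exactly."""
        rng = np.random.default_rng(5)
        genome, annA, annB = two_copy_genome(rng, library, "AluSx", 2_000,
                                             homology=43, crossover=150)
        donor, ev = apply_nahr_deletion(genome, annA, annB, 150, 43, library)
        call = self.run_one(genome, donor, library)
        assert call.mechanism == "NAHR_DEL"
        assert call.homology_len == 43
        assert call.deletion_track == "ARMD"
        assert (call.ref_start, call.ref_end) == (ev.ref_start, ev.ref_end)
        assert call.homology_cons_lo <= 150 < call.homology_cons_hi

    def test_nhej_with_engineered_microhomology(self, library):
        rng = np.random.default_rng(6)
        genome, annA, annB = two_copy_genome(rng, library, "AluSq2", 800)
        donor, ev = apply_nhej_deletion(genome, "chr1", annA.start + 150,
                                        annB.start + 200, 7, seed=2)
        call = self.run_one(genome, donor, library)
        assert call.mechanism == "NHEJ_DEL"
        assert call.microhomology_len == 7
        assert call.deleted_len == ev.deleted_len

    def test_blunt_nhej_junction_reports_zero(self, library):
        rng = np.random.default_rng(8)
        genome, annA, annB = two_copy_genome(rng, library, "AluSp", 900)
        donor, ev = apply_nhej_deletion(genome, "chr1", annA.start + 120,
                                        annB.start + 230, 0, seed=4)
        call = self.run_one(genome, donor, library)
        assert call.mechanism == "NHEJ_DEL"
        assert call.microhomology_len == 0

    def test_never_nahr_below_min_homology(self, small_run):
        _, result = small_run
        for call in result.calls:
            if call.mechanism == "NAHR_DEL":
                assert call.homology_len >= 3


class TestInsertionClassification:
    def test_ncai_with_large_target_deletion(self, rng, library):
        """A 139 bp element replacing 3270 bp is recovered as NCAI (net -3131)."""
        base = ReferenceGenome({"chr1": random_seq(rng, 40_000)}, [])
        donor, ev = apply_ncai(base, "chr1", 20_000, "AluYb9", trunc=(100, 239),
                               target_del_len=3_270, library=library)
        result = tk.run_calls(base.contigs, {"chr1": donor}, library,
                              PipelineConfig())
        (call,) = result.calls
        assert call.mechanism == "NCAI"
        assert call.pre_insertion_del_len == 3_270
        assert call.inserted_len - call.deleted_len == -3_131
        assert call.tsd_seq == ""

    def test_small_sim_recovers_all_mechanisms(self, small_run):
        sim, result = small_run
        from tasvkit.evaluate import evaluate_classification
        metrics = evaluate_classification(result.calls, sim.events)
        for mech, acc in metrics.per_mechanism_accuracy.items():
            assert acc == 1.0, (mech, metrics.confusion)

    def test_exactly_one_mechanism_per_call(self, small_run):
        _, result = small_run
        from tasvkit.genome import MECHANISMS
        for call in result.calls:
            assert call.mechanism in MECHANISMS + ("UNCLASSIFIED",)
            if call.mechanism != "NAHR_DEL":
                assert call.homology_len == 0
            if call.mechanism not in ("CLASSICAL_INS", "SOLITARY_LTR"):
                assert call.tsd_seq == ""
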