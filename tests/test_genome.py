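import pytest
from tasvkit.genome import (GenerationError, RepeatAnnotation, ReferenceGenome,
                            SimulationConfig, apply_classical_insertion,
                            apply_ltr_events, apply_ncai, apply_nahr_deletion,
                            apply_nhej_deletion, build_reference, simulate)
from tasvkit.library import LTR_BLOCK_LEN
from tasvkit.sequtil import random_seq


def plain_genome(rng, length=20_000, annotations=()):
    return ReferenceGenome({"chr1": random_seq(rng, length)}, list(annotations))


class TestBuildReference:
    def test_zero_densities(self):
        ref = build_reference(10_000, 1, {}, seed=0)
        assert len(ref.contigs["chr1"]) == 10_000
        assert ref.annotations == []

    def test_determinism(self):
        a = build_reference(50_000, 2, {"Alu": 0.1}, gene_fraction=0.2, seed=5)
        b = build_reference(50_000, 2, {"Alu": 0.1}, gene_fraction=0.2, seed=5)
        assert a.contigs == b.contigs
        assert a.annotations == b.annotations

    def test_infeasible_density_rejected(self):
        with pytest.raises(GenerationError):
            build_reference(10_000, 1, {"Alu": 0.5, "L1": 0.45}, seed=0)

    def test_annotations_record_planted_copies(self, library):
        ref = build_reference(100_000, 1, {"Alu": 0.1}, seed=3, library=library)
        planted = sum(len(a) for a in ref.annotations)
        assert abs(planted / 100_000 - 0.1) < 0.03
        for ann in ref.annotations:
            assert 0 <= ann.start < ann.end <= 100_000
            assert ann.subfamily in library


class TestClassicalInsertion:
    def test_length_arithmetic(self, rng, library):
        """300 bp element + 20 bp tail + one extra 12 bp TSD copy: donor gains
        332 bp (the reference already carries the target site once)."""
        genome = plain_genome(rng)
        donor, ev = apply_classical_insertion(
            genome, "chr1", 5_000, "AluYa5", tsd_len=12, trunc_5p=0,
            polyA_len=20, library=library)
        assert len(donor) - 20_000 == 300 + 20 + 12 == 332
        assert ev.net_change == 332
        assert ev.tsd == genome.contigs["chr1"][5_000:5_012]
        # both TSD copies flank element + poly-A in the donor
        assert donor[5_000:5_012] == donor[5_332:5_344] == ev.tsd

    def test_zero_tsd_makes_no_duplication(self, rng, library):
        genome = plain_genome(rng)
        donor, ev = apply_classical_insertion(
            genome, "chr1", 5_000, "AluYa5", tsd_len=0, trunc_5p=0,
            polyA_len=10, library=library)
        assert ev.tsd == ""
        assert ev.net_change == 310

    def test_truncation_guard(self, rng, library):
        with pytest.raises(ValueError, match="50 bp"):
            apply_classical_insertion(plain_genome(rng), "chr1", 100, "AluYa5",
                                      12, trunc_5p=260, polyA_len=5, library=library)


class TestNcai:
    def test_net_loss_example(self, rng, library):
        """A 139 bp truncated element replacing 3270 bp: net change -3131 bp."""
        genome = plain_genome(rng)
        donor, ev = apply_ncai(genome, "chr1", 4_000, "AluYb9", trunc=(100, 239),
                               target_del_len=3_270, library=library)
        assert ev.inserted_len == 139 and ev.deleted_len == 3_270
        assert ev.net_change == -3_131
        assert len(donor) - 20_000 == -3_131

    def test_zero_deletion_is_pure_insertion(self, rng, library):
        genome = plain_genome(rng)
        donor, ev = apply_ncai(genome, "chr1", 4_000, "AluYa5", trunc=(0, 200),
                               target_del_len=0, library=library)
        assert ev.net_change == ev.inserted_len == 200
        assert ev.tsd == "" and ev.polyA_len == 0

    def test_length_oracle_random_parameterizations(self, rng, library):
        genome = plain_genome(rng, 30_000)
        for _ in range(100):
            c0 = int(rng.integers(0, 150))
            c1 = int(rng.integers(c0 + 60, 300))
            del_len = int(rng.integers(0, 4_000))
            site = int(rng.integers(1_000, 25_000))
            donor, ev = apply_ncai(genome, "chr1", site, "AluYa5", (c0, c1),
                                   del_len, library=library)
            assert len(donor) == 30_000 + (c1 - c0) - del_len == 30_000 + ev.net_change


class TestNahr:
    def make_pair(self, rng, library, spacing=5_000):
        """Two identical full-length AluSx copies ``spacing`` apart."""
        cons = library["AluSx"].sequence
        seq = random_seq(rng, 30_000)
        seq = seq[:10_000] + cons + seq[10_300:]
        seq = seq[:10_000 + spacing] + cons + seq[10_000 + spacing + 300:]
        annA = RepeatAnnotation("chr1", 10_000, 10_300, "+", "AluSx", 0, 300, 0.0)
        annB = RepeatAnnotation("chr1", 10_000 + spacing, 10_300 + spacing, "+",
                                "AluSx", 0, 300, 0.0)
        return ReferenceGenome({"chr1": seq}, [annA, annB]), annA, annB

    def test_coordinate_arithmetic(self, rng, library):
        genome, annA, annB = self.make_pair(rng, library)
        donor, ev = apply_nahr_deletion(genome, annA, annB, crossover=150,
                                        homology_len=20, library=library)
        assert ev.deleted_len == 5_000
        assert len(donor) == 30_000 - 5_000
        # the chimera is one full-length element
        assert donor[10_000:10_300] == library["AluSx"].sequence

    def test_identical_copies_carry_full_homology(self, rng, library):
        genome, annA, annB = self.make_pair(rng, library)
        # identity check passes for the whole remaining consensus overlap
        _, ev = apply_nahr_deletion(genome, annA, annB, crossover=10,
                                    homology_len=290, library=library)
        assert ev.homology_len == 290

    def test_preconditions(self, rng, library):
        genome, annA, annB = self.make_pair(rng, library)
        with pytest.raises(ValueError, match="upstream"):
            apply_nahr_deletion(genome, annB, annA, 150, 10, library)
        l1 = RepeatAnnotation("chr1", 20_000, 21_000, "+", "L1HS", 0, 1_000, 0.0)
        with pytest.raises(ValueError, match="family"):
            apply_nahr_deletion(genome, annA, l1, 150, 10, library)
        with pytest.raises(ValueError, match="crossover"):
            apply_nahr_deletion(genome, annA, annB, 500, 10, library)

    def test_insufficient_identity_rejected(self, rng, library):
        genome, annA, annB = self.make_pair(rng, library)
        seq = genome.contigs["chr1"]
        # break the identity inside the would-be homology window of copy B
        pos = annB.start + 155
        seq = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
        genome.contigs["chr1"] = seq
        with pytest.raises(ValueError, match="identity"):
            apply_nahr_deletion(genome, annA, annB, 150, 20, library)


class TestNhej:
    def test_length_oracle_random_cases(self, rng):
        seq = random_seq(rng, 40_000)
        ann = RepeatAnnotation("chr1", 0, 40_000, "+", "AluSx", 0, 300, 0.0)
        for _ in range(100):
            genome = ReferenceGenome({"chr1": seq}, [ann])
            b5 = int(rng.integers(1_000, 20_000))
            b3 = b5 + int(rng.integers(50, 15_000))
            m = int(rng.integers(0, 19))
            donor, ev = apply_nhej_deletion(genome, "chr1", b5, b3, m, seed=int(rng.integers(1 << 30)))
            assert len(donor) == 40_000 - (b3 - b5)
            assert ev.deleted_len == b3 - b5

    @pytest.mark.parametrize("m", [0, 7, 18])
    def test_engineered_microhomology_is_exact(self, rng, m, library):
        from tasvkit.classify import measure_microhomology
        seq = random_seq(rng, 20_000)
        ann = RepeatAnnotation("chr1", 4_000, 12_000, "+", "L1HS", 0, 8_000, 0.0)
        genome = ReferenceGenome({"chr1": seq}, [ann])
        b5, b3 = 5_000, 9_000
        donor, ev = apply_nhej_deletion(genome, "chr1", b5, b3, m, seed=3)
        ref = genome.contigs["chr1"]
        measured = measure_microhomology(donor[b5 - 30:b5 + 30],
                                         ref[:b5], ref[b3 - m:], max_mh=30)
        assert measured == m == ev.microhomology_len

    def test_requires_te_anchor(self, rng):
        genome = ReferenceGenome({"chr1": random_seq(rng, 10_000)}, [])
        with pytest.raises(ValueError, match="TE"):
            apply_nhej_deletion(genome, "chr1", 2_000, 3_000, 5)


class TestLtrEvents:
    def test_solitary_ltr_length(self, rng, library):
        genome = plain_genome(rng)
        donor, ev = apply_ltr_events(genome, "chr1", "SOLITARY_LTR", 6_000,
                                     library, tsd_len=5)
        assert len(donor) - 20_000 == LTR_BLOCK_LEN + 5
        assert ev.net_change == 455

    def test_herv_internal_deletion_length(self, rng, library):
        cons = library["HERV-K"].sequence
        seq = random_seq(rng, 20_000)
        seq = seq[:8_000] + cons[:LTR_BLOCK_LEN] + seq[8_000 + LTR_BLOCK_LEN:]
        ann = RepeatAnnotation("chr1", 8_000, 8_000 + LTR_BLOCK_LEN, "+",
                               "HERV-K", 0, LTR_BLOCK_LEN, 0.0)
        genome = ReferenceGenome({"chr1": seq}, [ann])
        donor, ev = apply_ltr_events(genome, "chr1", "HERV_INTERNAL_DEL", ann,
                                     library, internal_keep=30)
        placed = 2 * LTR_BLOCK_LEN + 30
        assert len(donor) - 20_000 == placed - LTR_BLOCK_LEN
        assert ev.net_change == placed - LTR_BLOCK_LEN

    def test_variant_site_mismatch(self, rng, library):
        genome = plain_genome(rng)
        with pytest.raises(ValueError):
            apply_ltr_events(genome, "chr1", "HERV_INTERNAL_DEL", 5_000, library)
        with pytest.raises(ValueError):
            apply_ltr_events(genome, "chr1", "SOLITARY_LTR", "not-a-site", library)


class TestSimulate:
    def test_zero_events_donor_equals_reference(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=100_000, n_classical=0,
                               n_ncai=0, n_solitary_ltr=0, n_herv_internal_del=0,
                               n_nahr=0, n_nhej=0)
        sim = simulate(cfg, seed=4)
        assert sim.donor == sim.reference.contigs
        assert sim.events == []

    def test_event_counts_and_determinism(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=500_000, n_classical=10,
                               n_ncai=5, n_solitary_ltr=0, n_herv_internal_del=0,
                               n_nahr=10, n_nhej=5, n_nahr_l1=1, n_nhej_l1=1)
        a = simulate(cfg, seed=9)
        b = simulate(cfg, seed=9)
        assert len(a.events) == 30
        assert a.truth_table().equals(b.truth_table())
        assert a.donor == b.donor and a.reference.contigs == b.reference.contigs

    def test_conservation_per_contig(self, small_sim):
        for contig, ref_seq in small_sim.reference.contigs.items():
            signed = sum(ev.net_change for ev in small_sim.events
                         if ev.contig == contig)
            assert len(small_sim.donor[contig]) - len(ref_seq) == signed

    def test_truth_in_reference_coordinates(self, small_sim):
        for ev in small_sim.events:
            ref = small_sim.reference.contigs[ev.contig]
            assert 0 <= ev.ref_start <= ev.ref_end <= len(ref)
            if ev.mechanism == "CLASSICAL_INS":
                assert ref[ev.ref_start:ev.ref_start + len(ev.tsd)] == ev.tsd

    def test_classical_tsd_copies_exact_in_donor(self, small_sim):
        """Hallmark fidelity: both TSD copies are exact duplicates at divergence 0."""
        offsets = {c: 0 for c in small_sim.reference.contigs}
        for ev in sorted(small_sim.events, key=lambda e: (e.contig, e.ref_start)):
            if ev.mechanism == "CLASSICAL_INS":
                pos = ev.ref_start + offsets[ev.contig]
                donor = small_sim.donor[ev.contig]
                t = len(ev.tsd)
                assert donor[pos:pos + t] == ev.tsd
                right = pos + t + ev.inserted_len
                assert donor[right:right + t] == ev.tsd
            offsets[ev.contig] += ev.net_change

    def test_write_simulation_round_trip(self, small_sim, tmp_path):
        from tasvkit.genome import table_to_events, write_simulation
        from tasvkit.io import read_fasta, read_tsv_table
        paths = write_simulation(small_sim, tmp_path)
        assert read_fasta(paths["reference"]) == small_sim.reference.contigs
        assert read_fasta(paths["donor"]) == small_sim.donor
        events = table_to_events(read_tsv_table(paths["truth"]))
        assert events == small_sim.events
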