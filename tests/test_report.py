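import numpy as np
import pandas as pd
import pytest

from tasvkit.genome import GeneFeature, RepeatAnnotation
from tasvkit.report import (calls_to_accounting, combination_matrix,
                            compare_callsets, genic_overlap, size_histogram,
                            summarize, te_density)


def acc_row(cls="insertion", mechanism="CLASSICAL_INS", subfamily="AluYa5",
            inserted=300, deleted=0, tsd=0, contig="chr1", start=0, end=0):
    return {"class": cls, "mechanism": mechanism, "subfamily": subfamily,
            "family": "Alu", "contig": contig, "ref_start": start, "ref_end": end,
            "inserted_len": inserted, "deleted_len": deleted, "tsd_len": tsd,
            "status": "confirmed"}


class TestSummarize:
    def test_empty(self):
        out = summarize(pd.DataFrame())
        assert out.iloc[-1]["net_bp"] == 0

    def test_family_gains_reproduce_total(self):
        """Family-level insertion gains summed by the accounting: 64,232 bp."""
        gains = {"Alu": 49_608, "L1": 6_399, "SVA": 2_275, "LTR": 5_950}
        rows = [acc_row(subfamily=fam, inserted=bp) for fam, bp in gains.items()]
        out = summarize(pd.DataFrame(rows))
        total = out[out["key"] == "TOTAL"].iloc[0]
        assert total["bp_gained"] == 64_232

    def test_deletion_losses_reproduce_total(self):
        """Mechanism-track losses summed by the accounting: 82,772 bp."""
        losses = [("NAHR_DEL", "NAHR-ARMD", 42_909), ("NHEJ_DEL", "NHEJ-ARMD", 7_313),
                  ("NAHR_DEL", "NAHR-L1RAD", 3_177), ("NHEJ_DEL", "NHEJ-L1RAD", 29_373)]
        rows = [acc_row(cls="deletion", mechanism=m, subfamily=s, inserted=0,
                        deleted=bp) for m, s, bp in losses]
        out = summarize(pd.DataFrame(rows))
        assert out[out["key"] == "TOTAL"].iloc[0]["bp_lost"] == 82_772

    def test_ncai_row_carries_gain_and_loss(self):
        """139 bp inserted / 3270 bp target deletion: net -3131 on the row."""
        out = summarize(pd.DataFrame([acc_row(mechanism="NCAI", subfamily="AluYb9",
                                              inserted=139, deleted=3_270)]))
        row = out[out["key"] == "AluYb9"].iloc[0]
        assert (row["bp_gained"], row["bp_lost"], row["net_bp"]) == (139, 3_270, -3_131)

    def test_tsd_counted_once_for_classical(self):
        out = summarize(pd.DataFrame([acc_row(inserted=320, tsd=12)]))
        assert out[out["key"] == "TOTAL"].iloc[0]["bp_gained"] == 332

    def test_conserves_call_net_change(self, small_run):
        sim, result = small_run
        acc = calls_to_accounting(result.calls)
        out = summarize(acc)
        total_net = out[out["key"] == "TOTAL"].iloc[0]["net_bp"]
        tsd_gain = np.where(acc["mechanism"].isin(["CLASSICAL_INS", "SOLITARY_LTR"]),
                            acc["tsd_len"], 0)
        assert total_net == int((acc["inserted_len"] + tsd_gain
                                 - acc["deleted_len"]).sum())


class TestSizeHistogram:
    def test_binning(self):
        counts = size_histogram([200, 450, 800], bin_width=500)
        assert counts.to_dict() == {0: 2, 500: 1}

    def test_empty(self):
        assert size_histogram([]).empty

    def test_total_conserved(self, small_run):
        _, result = small_run
        dels = [c.deleted_len for c in result.calls if c.mechanism.endswith("_DEL")]
        assert int(size_histogram(dels).sum()) == len(dels)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            size_histogram([100], bin_width=0)


class TestCombinationMatrix:
    def make(self, pairs):
        return pd.DataFrame([{"mechanism": m, "partner1": a, "partner2": b}
                             for m, a, b in pairs])

    def test_pair_normalization(self):
        cm = combination_matrix(self.make([
            ("NAHR_DEL", "AluSx", "AluSx"),
            ("NAHR_DEL", "AluSx", "AluSx"),
            ("NAHR_DEL", "AluYa5", "AluSx"),
        ]))
        assert cm.pair_counts.loc["AluSx-AluSx", "NAHR_DEL"] == 2
        assert cm.pair_counts.loc["AluSx-AluYa5", "NAHR_DEL"] == 1
        assert cm.group_counts.loc["AluS-AluY", "NAHR_DEL"] == 1

    def test_rollup_conserves_count(self, small_run):
        _, result = small_run
        dels = [c for c in result.calls if c.mechanism.endswith("_DEL")]
        cm = combination_matrix(dels)
        assert cm.total == len(dels)
        assert int(cm.group_counts.to_numpy().sum()) == len(dels)

    def test_confirmed_armd_total(self):
        """51 NAHR + 26 NHEJ confirmed recombination deletions: total 77."""
        pairs = [("NAHR_DEL", "AluSx", "AluSz6")] * 51 + \
                [("NHEJ_DEL", "AluSq2", "AluYa5")] * 26
        assert combination_matrix(self.make(pairs)).total == 77


GENES = [
    GeneFeature("chr1", 1_000, 1_200, "g1", "UTR5"),
    GeneFeature("chr1", 1_200, 1_500, "g1", "exon"),
    GeneFeature("chr1", 1_500, 4_000, "g1", "intron"),
    GeneFeature("chr1", 4_000, 4_500, "g1", "UTR3"),
]


class TestGenicOverlap:
    def frame(self, rows):
        return pd.DataFrame(rows)

    def test_insertion_point_in_intron(self):
        calls = self.frame([{"contig": "chr1", "ref_start": 2_000, "ref_end": 2_000}])
        labels, counts = genic_overlap(calls, GENES)
        assert list(labels) == ["intron"] and counts["intron"] == 1

    def test_insertion_outside_genes(self):
        calls = self.frame([{"contig": "chr1", "ref_start": 9_000, "ref_end": 9_000}])
        labels, _ = genic_overlap(calls, GENES)
        assert list(labels) == ["intergenic"]

    def test_deletion_majority_label(self):
        # 60% of the interval is intronic, 40% beyond the gene end
        calls = self.frame([{"contig": "chr1", "ref_start": 3_400,
                             "ref_end": 4_900}])
        feats = GENES[:3] + [GeneFeature("chr1", 4_000, 4_300, "g1", "UTR3")]
        labels, _ = genic_overlap(calls, feats)
        assert list(labels) == ["intron"]

    def test_counts_sum_to_calls(self, small_run):
        sim, result = small_run
        acc = calls_to_accounting(result.calls)
        labels, counts = genic_overlap(acc, sim.reference.genes)
        assert int(counts.sum()) == len(result.calls)


class TestTeDensity:
    def ann(self, start, end, sub="AluSx"):
        return RepeatAnnotation("chr1", start, end, "+", sub, 0, end - start, 5.0)

    def test_single_alu_fraction(self, library):
        genes = [GeneFeature("chr1", 0, 1_000, "g", "exon")]
        dens = te_density(genes, [self.ann(100, 400)], {"Alu"}, library)
        assert dens["g"] == pytest.approx(0.30)

    def test_no_repeats(self, library):
        genes = [GeneFeature("chr1", 0, 1_000, "g", "exon")]
        assert te_density(genes, [], {"Alu"}, library)["g"] == 0.0

    def test_overlapping_copies_counted_once(self, library):
        genes = [GeneFeature("chr1", 0, 1_000, "g", "exon")]
        dens = te_density(genes, [self.ann(100, 400), self.ann(300, 450)],
                          {"Alu"}, library)
        assert dens["g"] == pytest.approx(0.35)

    def test_zero_length_gene_rejected(self, library):
        with pytest.raises(ValueError):
            te_density([GeneFeature("chr1", 5, 5, "g", "exon")], [], {"Alu"}, library)


class TestCompareCallsets:
    def sets(self, positions_a, positions_b):
        a = pd.DataFrame({"contig": "chr1", "pos": positions_a})
        b = pd.DataFrame({"contig": "chr1", "pos": positions_b})
        return a, b

    def test_identical_sets(self):
        a, b = self.sets([100, 5_000, 9_999], [100, 5_000, 9_999])
        cmp_res = compare_callsets(a, b)
        assert len(cmp_res.matches) == 3
        assert cmp_res.mean_abs_error == 0.0
        assert not cmp_res.unmatched_a and not cmp_res.unmatched_b

    def test_shifted_by_four(self):
        """A +4 bp systematic shift yields mean |error| of exactly 4 bp."""
        pos = [100, 700, 2_300, 8_100, 40_000]
        a, b = self.sets(pos, [p + 4 for p in pos])
        cmp_res = compare_callsets(a, b, tolerance=100)
        assert len(cmp_res.matches) == len(pos)
        assert cmp_res.mean_abs_error == 4.0
        assert (cmp_res.matches["error"] == 4).all()

    def test_beyond_tolerance_unmatched(self):
        a, b = self.sets([100], [300])
        cmp_res = compare_callsets(a, b, tolerance=100)
        assert cmp_res.matches.empty
        assert cmp_res.unmatched_a == [0] and cmp_res.unmatched_b == [0]

    def test_symmetry_up_to_sign(self, rng):
        pa = sorted(int(x) for x in rng.integers(0, 10**6, 40))
        pb = [p + int(rng.integers(-80, 80)) for p in pa[:30]] + \
             [int(x) for x in rng.integers(0, 10**6, 5)]
        a, b = self.sets(pa, pb)
        fwd = compare_callsets(a, b)
        rev = compare_callsets(b, a)
        assert sorted(fwd.matches["error"]) == sorted(-rev.matches["error"])
        assert sorted(fwd.unmatched_a) == sorted(rev.unmatched_b)
        assert sorted(fwd.unmatched_b) == sorted(rev.unmatched_a)

    def test_matching_is_one_to_one(self):
        a, b = self.sets([100, 110], [105])
        cmp_res = compare_callsets(a, b, tolerance=50)
        assert len(cmp_res.matches) == 1
        # nearest pair wins: 105 matches 100? |105-100|=5 == |110-105|=5; tie
        # breaks on the lower A coordinate
        assert cmp_res.matches.iloc[0]["idx_a"] == 0
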