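"""Accounting and comparison: per-subfamily/mechanism summary tables, deletion size
histograms, recombination-partner matrices, genic overlap, per-gene TE density, and
positional comparison between two callsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classify import JunctionCall
from .genome import GeneFeature, RepeatAnnotation, TSD_MECHANISMS, INSERTION_MECHANISMS


def calls_to_accounting(calls: list[JunctionCall]) -> pd.DataFrame:
    """Flatten classified calls into the accounting schema summarize() consumes."""
    rows = []
    for c in calls:
        rows.append({
            "class": ("insertion" if c.mechanism in INSERTION_MECHANISMS
                      else "deletion" if c.mechanism.endswith("_DEL")
                      else "unclassified"),
            "mechanism": c.mechanism,
            "subfamily": c.subfamily or ".",
            "family": c.family or ".",
            "contig": c.contig,
            "ref_start": c.ref_start,
            "ref_end": c.ref_end,
            "inserted_len": c.inserted_len,
            "deleted_len": c.deleted_len,
            "tsd_len": len(c.tsd_seq),
            "status": "confirmed",
        })
    return pd.DataFrame(rows)


def summarize(calls: pd.DataFrame | list[JunctionCall]) -> pd.DataFrame:
    """Per-(class, subfamily-or-mechanism) counts and bp bookkeeping, with totals.

    bp gained counts inserted sequence plus the duplicated target site for
    TSD-generating mechanisms; bp lost counts deleted reference sequence. NCAI
    rows therefore carry both a gain and a loss component. The TOTAL row's net
    equals the signed sum of per-call net changes.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = calls_to_accounting(calls)
    cols = ["class", "key", "candidate_n", "filtered_n", "confirmed_n",
            "bp_gained", "bp_lost", "net_bp"]
    if calls.empty:
        out = pd.DataFrame(columns=cols)
        out.loc[0] = ["TOTAL", "TOTAL", 0, 0, 0, 0, 0, 0]
        return out

    df = calls.copy()
    if "status" not in df:
        df["status"] = "confirmed"
    if "tsd_len" not in df:
        df["tsd_len"] = 0
    df["key"] = np.where(df["class"] == "insertion", df["subfamily"],
                         df["mechanism"].astype(str))
    tsd_gain = np.where(df["mechanism"].isin(list(TSD_MECHANISMS)), df["tsd_len"], 0)
    df["gain"] = np.where(df["status"] == "confirmed", df["inserted_len"] + tsd_gain, 0)
    df["loss"] = np.where(df["status"] == "confirmed", df["deleted_len"], 0)

    rows = []
    for (cls, key), grp in df.groupby(["class", "key"], sort=True):
        rows.append({
            "class": cls, "key": key,
            "candidate_n": len(grp),
            "filtered_n": int((grp["status"] == "filtered").sum()),
            "confirmed_n": int((grp["status"] == "confirmed").sum()),
            "bp_gained": int(grp["gain"].sum()),
            "bp_lost": int(grp["loss"].sum()),
            "net_bp": int(grp["gain"].sum() - grp["loss"].sum()),
        })
    out = pd.DataFrame(rows, columns=cols)
    total = {
        "class": "TOTAL", "key": "TOTAL",
        "candidate_n": int(out["candidate_n"].sum()),
        "filtered_n": int(out["filtered_n"].sum()),
        "confirmed_n": int(out["confirmed_n"].sum()),
        "bp_gained": int(out["bp_gained"].sum()),
        "bp_lost": int(out["bp_lost"].sum()),
        "net_bp": int(out["net_bp"].sum()),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def size_histogram(deletion_sizes: Iterable[int] | pd.DataFrame,
                   bin_width: int = 500) -> pd.Series:
    """Counts of deletion sizes per half-open bin [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(deletion_sizes, pd.DataFrame):
        sizes = deletion_sizes["deleted_len"].to_numpy()
    else:
        sizes = np.asarray(list(deletion_sizes), dtype=int)
    if len(sizes) == 0:
        return pd.Series(dtype=int)
    bins = sizes // bin_width
    counts = pd.Series(bins).value_counts().sort_index()
    counts.index = counts.index * bin_width
    return counts


_ALU_GROUPS = ("AluY", "AluS", "AluJ")


def _family_group(subfamily: str) -> str:
    for g in _ALU_GROUPS:
        if subfamily.startswith(g):
            return g
    if subfamily.startswith("Alu") or subfamily in ("FLAM", "FRAM"):
        return "Alu-other"
    if subfamily.startswith("L1"):
        return "L1"
    return subfamily


@dataclass
class CombinationMatrix:
    pair_counts: pd.DataFrame      # rows: normalized subfamily pair; cols: mechanism
    group_counts: pd.DataFrame     # same, rolled up to AluJ/AluS/AluY etc.

    @property
    def total(self) -> int:
        return int(self.pair_counts.to_numpy().sum())


def combination_matrix(deletion_calls: list[JunctionCall] | pd.DataFrame) -> CombinationMatrix:
    """Partner-subfamily pair counts for recombination deletions, by mechanism.

    Pairs are order-normalized (lexicographic); a family-level roll-up
    (AluJ/AluS/AluY) is included. The roll-up total equals the input call count.
    """
    if isinstance(deletion_calls, pd.DataFrame):
        records = deletion_calls.to_dict("records")
    else:
        records = [{"mechanism": c.mechanism, "partner1": c.partner1,
                    "partner2": c.partner2} for c in deletion_calls]
    pair_rows, group_rows = [], []
    for r in records:
        p1, p2 = sorted([str(r["partner1"]), str(r["partner2"])])
        pair_rows.append({"pair": f"{p1}-{p2}", "mechanism": r["mechanism"]})
        g1, g2 = sorted([_family_group(p1), _family_group(p2)])
        group_rows.append({"pair": f"{g1}-{g2}", "mechanism": r["mechanism"]})

    def pivot(rows):
        if not rows:
            return pd.DataFrame()
        df = pd.DataFrame(rows)
        return df.pivot_table(index="pair", columns="mechanism", aggfunc="size",
                              fill_value=0)

    return CombinationMatrix(pivot(pair_rows), pivot(group_rows))


def genic_overlap(calls: pd.DataFrame | list[JunctionCall],
                  gene_model: Sequence[GeneFeature]) -> tuple[pd.Series, pd.Series]:
    """Label calls by gene sub-feature: insertions by point, deletions by majority.

    Returns (per-call labels, per-label counts). Calls overlapping several genes
    are labeled by the first gene in coordinate order.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = calls_to_accounting(calls)
    trees: dict[str, IntervalTree] = {}
    for feat in gene_model:
        trees.setdefault(feat.contig, IntervalTree()).addi(
            feat.start, feat.end, (feat.gene, feat.feature))

    labels = []
    for row in calls.itertuples():
        tree = trees.get(row.contig)
        if tree is None:
            labels.append("intergenic")
            continue
        if row.ref_end <= row.ref_start:  # insertion point
            hits = sorted(tree.at(row.ref_start), key=lambda iv: (iv.begin, iv.data))
            labels.append(hits[0].data[1] if hits else "intergenic")
            continue
        span = row.ref_end - row.ref_start
        hits = sorted(tree.overlap(row.ref_start, row.ref_end),
                      key=lambda iv: (iv.begin, iv.data))
        first_gene = hits[0].data[0] if hits else None
        cover: dict[str, int] = {}
        for iv in hits:
            if iv.data[0] != first_gene:
                continue
            cover[iv.data[1]] = cover.get(iv.data[1], 0) + (
                min(iv.end, row.ref_end) - max(iv.begin, row.ref_start))
        genic_bp = sum(cover.values())
        if genic_bp * 2 < span or not cover:
            labels.append("intergenic")
        else:
            labels.append(max(sorted(cover), key=lambda k: cover[k]))
    label_series = pd.Series(labels, index=calls.index, name="feature")
    return label_series, label_series.value_counts()


def te_density(gene_model: Sequence[GeneFeature],
               repeat_annotations: Sequence[RepeatAnnotation],
               families: set[str], library) -> pd.Series:
    """Per-gene repeat density: union bp of requested-family repeats / gene length.

    Overlapping repeat bp is counted once (interval union), so densities never
    exceed 1.
    """
    spans: dict[str, tuple[str, int, int]] = {}
    for feat in gene_model:
        if feat.gene in spans:
            c, s, e = spans[feat.gene]
            spans[feat.gene] = (c, min(s, feat.start), max(e, feat.end))
        else:
            spans[feat.gene] = (feat.contig, feat.start, feat.end)

    anns = [(a.contig, a.start, a.end) for a in repeat_annotations
            if library.family_of(a.subfamily) in families]
    anns.sort()
    out = {}
    for gene, (contig, g0, g1) in sorted(spans.items()):
        if g1 <= g0:
            raise ValueError(f"zero-length gene {gene}")
        pieces = sorted((max(s, g0), min(e, g1)) for c, s, e in anns
                        if c == contig and s < g1 and e > g0)
        covered = 0
        cur_s, cur_e = None, None
        for s, e in pieces:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        out[gene] = covered / (g1 - g0)
    return pd.Series(out, name="density")


@dataclass
class CallsetComparison:
    matches: pd.DataFrame          # idx_a, idx_b, error (signed, B - A)
    unmatched_a: list
    unmatched_b: list
    tolerance: int

    @property
    def mean_abs_error(self) -> float:
        if self.matches.empty:
            return float("nan")
        return float(self.matches["error"].abs().mean())


def compare_callsets(set_a: pd.DataFrame, set_b: pd.DataFrame,
                     tolerance: int = 100) -> CallsetComparison:
    """Greedy nearest-neighbor one-to-one matching of two callsets.

    Input frames need columns contig and pos (and optionally kind, matched only
    within the same kind). Pairs are taken by increasing |distance| with a
    deterministic tie-break (lower A coordinate, then lower B coordinate); the
    signed error is pos_b - pos_a.
    """
    a = set_a.reset_index(drop=True)
    b = set_b.reset_index(drop=True)
    use_kind = "kind" in a.columns and "kind" in b.columns
    pairs = []
    for ia, ra in a.iterrows():
        for ib, rb in b.iterrows():
            if ra["contig"] != rb["contig"]:
                continue
            if use_kind and ra["kind"] != rb["kind"]:
                continue
            d = int(rb["pos"]) - int(ra["pos"])
            if abs(d) <= tolerance:
                pairs.append((abs(d), int(ra["pos"]), int(rb["pos"]), ia, ib, d))
    pairs.sort()
    used_a, used_b, rows = set(), set(), []
    for _, _, _, ia, ib, d in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append({"idx_a": ia, "idx_b": ib, "error": d})
    matches = pd.DataFrame(rows, columns=["idx_a", "idx_b", "error"])
    return CallsetComparison(
        matches=matches,
        unmatched_a=[i for i in a.index if i not in used_a],
        unmatched_b=[i for i in b.index if i not in used_b],
        tolerance=tolerance,
    )
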