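"""Shared on-disk formats: FASTA, BED, TSV tables, flat config files, run manifests.

All genomic intervals are 0-based half-open everywhere in this package; BED files
on disk follow the same convention, so no shifting happens at the boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("tasvkit")

FASTA_WRAP = 60


class FormatError(ValueError):
    """Malformed record in an input file; message names file, line and reason."""


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping.

    CRLF line endings are accepted and normalized by the underlying parser.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | os.PathLike, records: Mapping[str, str]) -> None:
    """Write name -> sequence records, line-wrapped to 60 columns."""
    recs = (SeqRecord(Seq(s), id=str(n), description="") for n, s in records.items())
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(recs)


@dataclass
class BedRecord:
    contig: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    """Read a (up to) 6-column BED file, 0-based half-open."""
    records = []
    path = Path(path)
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if not 0 <= start < end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start},{end})")
            rec = BedRecord(parts[0], start, end)
            if len(parts) > 3:
                rec.name = parts[3]
            if len(parts) > 4:
                rec.score = parts[4]
            if len(parts) > 5:
                if parts[5] not in {"+", "-", "."}:
                    raise FormatError(f"{path}:{lineno}: bad strand {parts[5]!r}")
                rec.strand = parts[5]
            records.append(rec)
    return records


def write_bed(path: str | os.PathLike, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def read_tsv_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "donor_contig": str})


def write_tsv_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated parameters for the annotate -> mine -> classify -> report run.

    Paths may be None when a stage is configured directly from in-memory objects.
    """

    library: str | None = None
    reference: str | None = None
    donor: str | None = None
    gene_model: str | None = None
    known_sites: str | None = None
    outdir: str = "tasv_out"
    seed: int = 0

    flank_len: int = 2000              # bp of donor flank extracted on each side
    min_insertion_len: int = 100       # paper's insertion size filter
    max_tsd: int = 30
    min_tsd: int = 5
    tsd_max_mismatch_frac: float = 0.10
    min_homology: int = 3              # NAHR floor; paper's observed minimum
    match_tolerance: int = 100         # callset comparison tolerance, bp
    annotator_k: int = 13
    annotator_band: int = 32
    max_divergence: float = 25.0
    min_hit_len: int = 50
    adjacency_gap: int = 50            # reference gap at/below which flanks are "adjacent"
    placement_min_identity: float = 0.95
    placement_ambiguity_margin: float = 0.02
    ltr_block_len: int = 450

    _RANGES = {
        "flank_len": (500, 4000),
        "min_insertion_len": (0, 10_000),
        "max_tsd": (5, 100),
        "min_tsd": (1, 50),
        "tsd_max_mismatch_frac": (0.0, 0.5),
        "min_homology": (1, 1000),
        "match_tolerance": (0, 100_000),
        "annotator_k": (8, 31),
        "annotator_band": (4, 256),
        "max_divergence": (0.0, 50.0),
        "min_hit_len": (20, 10_000),
        "adjacency_gap": (0, 1000),
        "placement_min_identity": (0.5, 1.0),
        "placement_ambiguity_margin": (0.0, 0.5),
        "ltr_block_len": (50, 5000),
    }

    def validate(self) -> "PipelineConfig":
        for key, (lo, hi) in self._RANGES.items():
            val = getattr(self, key)
            if not lo <= val <= hi:
                raise ValueError(f"config parameter {key}={val} outside [{lo}, {hi}]")
        if self.min_tsd > self.max_tsd:
            raise ValueError("min_tsd must not exceed max_tsd")
        return self


def parse_flat_config(path: str | os.PathLike) -> dict[str, str]:
    """Parse a flat key=value config file. Blank lines and #-comments skipped."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key in out:
                raise FormatError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = value.strip()
    return out


def apply_config(cls, mapping: Mapping[str, str], **overrides):
    """Build a config dataclass from string values; unknown keys are errors."""
    known = {f.name: f for f in fields(cls) if not f.name.startswith("_")}
    kwargs = {}
    for key, raw in mapping.items():
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        ftype = known[key].type
        if "int" in str(ftype):
            kwargs[key] = int(raw)
        elif "float" in str(ftype):
            kwargs[key] = float(raw)
        elif "bool" in str(ftype):
            kwargs[key] = raw.lower() in {"1", "true", "yes"}
        elif "dict" in str(ftype):
            kwargs[key] = json.loads(raw)
        else:
            kwargs[key] = raw
    kwargs.update(overrides)
    return cls(**kwargs)


def config_to_text(cfg) -> str:
    lines = []
    for f in fields(cfg):
        if f.name.startswith("_"):
            continue
        val = getattr(cfg, f.name)
        if isinstance(val, dict):
            val = json.dumps(val)
        lines.append(f"{f.name}={val}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def file_checksum(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str = ""
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
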