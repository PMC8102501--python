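"""Repeat-consensus library: named subfamily consensus sequences keyed by family.

The library drives every other stage: the simulator plants diverged copies of these
consensi, the annotator assigns hits back to them, and the classifier localizes
truncations and recombination crossovers in consensus coordinates.

Header grammar on disk (plain FASTA has no metadata channel):

    >NAME|FAMILY|young     or     >NAME|FAMILY|old

FAMILY is one of Alu, L1, SVA, LTR. "young" marks retrotranspositionally active
subfamilies — the ones whose copies can be polymorphic between individuals and are
therefore the anchors of insertion mining.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import FormatError, read_fasta, write_fasta

FAMILIES = ("Alu", "L1", "SVA", "LTR")
_ALPHABET = set("ACGT")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TEConsensus:
    name: str
    family: str
    sequence: str
    young: bool

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if not self.sequence:
            raise ValueError(f"{self.name}: empty consensus sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in _ALPHABET), None)
        if bad is not None:
            raise ValueError(
                f"{self.name}: non-ACGT character {self.sequence[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ConsensusLibrary:
    """Ordered collection of TEConsensus with loud name lookup."""

    def __init__(self, entries: list[TEConsensus]):
        self.entries = list(entries)
        self._index: dict[str, TEConsensus] = {}
        for e in self.entries:
            if e.name in self._index:
                raise ValueError(f"duplicate subfamily name in library: {e.name!r}")
            self._index[e.name] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> TEConsensus:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"subfamily {name!r} not in consensus library") from None

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def family_of(self, name: str) -> str:
        return self[name].family

    def by_family(self, family: str) -> list[TEConsensus]:
        return [e for e in self.entries if e.family == family]


def _parse_header(header: str) -> tuple[str, str, bool]:
    parts = header.split("|")
    if len(parts) != 3:
        raise FormatError(
            f"malformed consensus header {header!r}: expected NAME|FAMILY|young-or-old"
        )
    name, family, flag = (p.strip() for p in parts)
    if flag not in {"young", "old"}:
        raise FormatError(f"record {name!r}: age flag must be 'young' or 'old', got {flag!r}")
    return name, family, flag == "young"


def load_library(path: str | Path) -> ConsensusLibrary:
    """Load and validate a consensus library from tagged-header FASTA."""
    entries = []
    for header, seq in read_fasta(path).items():
        name, family, young = _parse_header(header)
        try:
            entries.append(TEConsensus(name, family, seq, young))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return ConsensusLibrary(entries)


def write_library(lib: ConsensusLibrary, path: str | Path) -> None:
    recs = {
        f"{e.name}|{e.family}|{'young' if e.young else 'old'}": e.sequence for e in lib
    }
    write_fasta(path, recs)


def young_subfamilies(lib: ConsensusLibrary) -> set[str]:
    """Names of the retrotranspositionally active subfamilies."""
    return {e.name for e in lib if e.young}


# ---------------------------------------------------------------------------
# Bundled toy library
# ---------------------------------------------------------------------------
# Synthetic, seed-fixed consensus sequences; real consensus FASTA (Repbase/Dfam
# exports) can be supplied by the user through the same loader. Subfamilies within
# a family are derived from a shared ancestral sequence with a fixed number of
# diagnostic substitutions so that subfamily assignment is a meaningful problem.

_LIBRARY_SEED = 708178  # fixed: the bundled library must be identical across runs

ALU_LEN = 300
L1_LEN = 6000
SVA_LEN = 1200
LTR_BLOCK_LEN = 450
HERV_INTERNAL_LEN = 70  # full HERV-K model: LTR + internal + identical LTR = 970 bp

YOUNG_ALU = (
    "AluYa5", "AluYa8", "AluYb8", "AluYb9", "AluYc3",
    "AluYd8", "AluYg6", "AluYh9", "AluYk11", "AluYk12",
)
OLD_ALU = ("AluY", "AluSx", "AluSz6", "AluSq2", "AluSp", "AluJb", "AluJo")
SVA_NAMES = ("SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def default_library() -> ConsensusLibrary:
    """The bundled toy library.

    Young set (18 names): L1HS, the 10 AluY subfamilies mined in the source study,
    HERV-K, and SVA_A..SVA_F. Old relatives are included as recombination partners.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    entries: list[TEConsensus] = []

    alu_base = _random_seq(rng, ALU_LEN)
    for name in YOUNG_ALU:
        entries.append(TEConsensus(name, "Alu", _mutate(rng, alu_base, 8), True))
    for name in OLD_ALU:
        n = 15 if name.startswith(("AluS", "AluY")) else 25
        entries.append(TEConsensus(name, "Alu", _mutate(rng, alu_base, n), False))

    l1_base = _random_seq(rng, L1_LEN)
    entries.append(TEConsensus("L1HS", "L1", l1_base, True))
    entries.append(TEConsensus("L1PA3", "L1", _mutate(rng, l1_base, 120), False))
    entries.append(TEConsensus("L1PA5", "L1", _mutate(rng, l1_base, 200), False))

    sva_base = _random_seq(rng, SVA_LEN)
    for name in SVA_NAMES:
        entries.append(TEConsensus(name, "SVA", _mutate(rng, sva_base, 25), True))

    ltr_block = _random_seq(rng, LTR_BLOCK_LEN)
    internal = _random_seq(rng, HERV_INTERNAL_LEN)
    entries.append(TEConsensus("HERV-K", "LTR", ltr_block + internal + ltr_block, True))

    return ConsensusLibrary(entries)
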