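"""Regulatory-neutral mutation operators.

A spacer sequence must hold two promoters apart without regulating
either of them.  The operator used throughout is the *non-complementary
transversion*: each base has exactly two transversion partners
(purine <-> pyrimidine) and one of them is its Watson-Crick complement,
so excluding the complement forces a unique mapping

    A -> C,  C -> A,  G -> T,  T -> G

which is an involution.  Replacing bases by this map destroys protein
binding sites while leaving composition-like properties (purine content,
strand asymmetry) maximally perturbed in a defined, reversible way --
and, unlike the complement, never recreates the original duplex.

The module provides the parity/block selection patterns used to build
spacers (every other bp, odd/even phased tandem duplicates), composition
scrambling, and the scanning-block mutant series used to map remote
control elements inside enhancers.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterator

from .seqcore import NucSeq, SequenceError

__all__ = [
    "NC_TRANSVERSION",
    "TRANSITION",
    "MutationSpec",
    "ScanMutant",
    "ScanSeries",
    "nc_transversion",
    "apply_mutation_pattern",
    "every_other",
    "build_tandem_spacer",
    "scramble_composition",
    "scanning_series",
]

NC_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_NC_TABLE = str.maketrans("ACGT", "CATG")


def nc_transversion(b: str) -> str:
    """The unique transversion of ``b`` that is not its complement."""
    try:
        return NC_TRANSVERSION[b.upper()]
    except KeyError:
        raise SequenceError(f"base must be one of A/C/G/T, got {b!r}") from None


@dataclass(frozen=True)
class MutationSpec:
    """Which positions to hit: all, 1-based odd, 1-based even, or a block.

    ``block_start``/``block_len`` are 1-based and only legal in block mode.
    """

    mode: str
    block_start: int | None = None
    block_len: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all", "odd", "even", "block"):
            raise SequenceError(f"unknown mutation mode {self.mode!r}")
        if self.mode == "block":
            if not self.block_start or not self.block_len or self.block_start < 1 or self.block_len < 1:
                raise SequenceError("block mode needs 1-based block_start and block_len >= 1")
        elif self.block_start is not None or self.block_len is not None:
            raise SequenceError(f"block interval is only meaningful in block mode, not {self.mode!r}")


def apply_mutation_pattern(s: NucSeq, spec: MutationSpec) -> NucSeq:
    """Apply non-complementary transversions at the positions ``spec`` selects."""
    n = len(s)
    if spec.mode == "all":
        return s.with_bases(s.bases.translate(_NC_TABLE))
    chars = list(s.bases)
    if spec.mode in ("odd", "even"):
        start0 = 0 if spec.mode == "odd" else 1  # 1-based parity -> 0-based offset
        for i in range(start0, n, 2):
            chars[i] = NC_TRANSVERSION[chars[i]]
    else:
        lo, ln = spec.block_start, spec.block_len
        if lo + ln - 1 > n:
            raise SequenceError(
                f"block {lo}..{lo + ln - 1} outside sequence of length {n}"
            )
        for i in range(lo - 1, lo - 1 + ln):
            chars[i] = NC_TRANSVERSION[chars[i]]
    return s.with_bases("".join(chars))


def every_other(s: NucSeq, phase: str = "odd") -> NucSeq:
    """Mutate every other bp.  ``phase`` picks which 1-based parity is hit;
    the default (odd) is a configuration choice, not a biological claim."""
    return apply_mutation_pattern(s, MutationSpec(phase))


def build_tandem_spacer(unit: NucSeq) -> NucSeq:
    """Tandem-duplicate spacer: odd-mutated copy followed by even-mutated copy.

    The two copies carry complementary mutation phases, so aligning copy 1
    against copy 2 shows a difference at *every* position: wherever copy 1
    kept the original base, copy 2 mutated it, and vice versa.  The result
    is twice the unit length and shares no intact duplicated unit.
    """
    if len(unit) == 0:
        raise SequenceError("tandem spacer unit must be non-empty")
    if unit.is_circular:
        raise SequenceError("tandem spacer unit must be linear")
    first = apply_mutation_pattern(unit, MutationSpec("odd"))
    second = apply_mutation_pattern(unit, MutationSpec("even"))
    return NucSeq(f"{unit.id}_tandem2x", first.bases + second.bases)


def scramble_composition(s: NucSeq, seed: int) -> NucSeq:
    """Uniform random permutation of the bases, deterministic in ``seed``.

    Fisher-Yates via :class:`random.Random` -- the base multiset (hence GC
    content) is exactly preserved while all positional information is lost.
    """
    if s.is_circular:
        raise SequenceError("scramble operates on linear sequences")
    chars = list(s.bases)
    random.Random(seed).shuffle(chars)
    return s.with_bases("".join(chars))


@dataclass(frozen=True)
class ScanMutant:
    """One member of a scanning series: the mutant and its 1-based block."""

    seq: NucSeq
    start: int
    end: int


@dataclass(frozen=True)
class ScanSeries:
    """A 5'->3' tiling of block mutants over a parent sequence."""

    parent: NucSeq
    block_len: int
    mutants: tuple[ScanMutant, ...]

    def __len__(self) -> int:
        return len(self.mutants)

    def __iter__(self) -> Iterator[ScanMutant]:
        return iter(self.mutants)

    def manifest_rows(self) -> list[tuple[str, int, int, str]]:
        """(mutant id, block start, block end, parent id) rows for a TSV."""
        return [(m.seq.id, m.start, m.end, self.parent.id) for m in self.mutants]


def scanning_series(enh: NucSeq, block_len: int) -> ScanSeries:
    """Tile ``enh`` left-to-right with non-overlapping mutant blocks.

    Mutant *i* carries non-complementary transversions across block *i*
    only; a short final block is emitted as its own mutant.  The mutant
    count is ``ceil(len(enh) / block_len)``.
    """
    n = len(enh)
    if block_len < 1:
        raise SequenceError("block_len must be >= 1")
    if block_len > n:
        raise SequenceError(f"block_len {block_len} exceeds sequence length {n}")
    mutants = []
    for i in range(math.ceil(n / block_len)):
        start = i * block_len + 1
        ln = min(block_len, n - (start - 1))
        mut = apply_mutation_pattern(enh, MutationSpec("block", start, ln))
        mutants.append(
            ScanMutant(mut.with_bases(mut.bases, id=f"{enh.id}_scan{i + 1:03d}"), start, start + ln - 1)
        )
    return ScanSeries(enh, block_len, tuple(mutants))
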