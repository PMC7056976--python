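"""DNA primitives shared by every other module.

The substrate of the whole toolkit is a concrete DNA sequence
(:class:`NucSeq`) that is either linear or circular, plus an IUPAC
degenerate pattern type (:class:`DegeneratePattern`) used for motif and
restriction-site scanning and for degenerate primers.  Annotated vector
maps are :class:`ConstructMap` objects and round-trip through GenBank
flat files; bare sequences round-trip through FASTA.

Coordinate convention
---------------------
Internally every interval is 0-based half-open.  Positions cross the API
boundary (``Feature``, scrub reports, GenBank records) as 1-based
inclusive, which is the convention molecular biologists and the GenBank
format use.  On a circular sequence the origin is index 0 and an
origin-spanning feature is represented with ``start > end`` (written to
GenBank as a ``join(...)`` of the two arcs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from itertools import product as _iproduct
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC",
    "SequenceError",
    "NucSeq",
    "DegeneratePattern",
    "Feature",
    "ConstructMap",
    "complement",
    "revcomp",
    "reverse_complement",
    "iupac_match",
    "circularly_equal",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "genbank_to_string",
]

#: Expansion sets of the 15 IUPAC nucleotide codes.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Complement table covers the degenerate codes too, so patterns and primers
# can be reverse-complemented with the same machinery as concrete DNA.
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_CONCRETE = frozenset("ACGT")


class SequenceError(ValueError):
    """Raised for malformed sequences, patterns, or flat-file records."""


def complement(text: str) -> str:
    """IUPAC-aware complement of ``text`` (no reversal)."""
    return text.translate(_COMPLEMENT)


def revcomp(text: str) -> str:
    """Watson-Crick reverse complement of a (possibly degenerate) string."""
    return text.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSeq:
    """A concrete DNA sequence with an identifier and a topology.

    ``bases`` is canonicalised to uppercase; any character outside
    ``{A, C, G, T}`` rejects.  Degenerate codes are deliberately illegal
    here -- designed sequences are always concrete; ambiguity lives only
    in :class:`DegeneratePattern` and primers.
    """

    id: str
    bases: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not _CONCRETE.issuperset(bases):
            bad = sorted(set(bases) - _CONCRETE)
            raise SequenceError(
                f"sequence {self.id!r}: illegal characters {bad}; only A/C/G/T allowed"
            )
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def with_bases(self, bases: str, id: str | None = None) -> "NucSeq":
        return NucSeq(id if id is not None else self.id, bases, self.topology)

    def window(self, start: int, length: int) -> str:
        """0-based window of ``length`` bases; wraps the origin when circular."""
        n = len(self.bases)
        start %= n if self.is_circular else 1 if n == 0 else n
        if self.is_circular:
            doubled = self.bases + self.bases
            if length > n:
                raise SequenceError("window longer than circular sequence")
            return doubled[start : start + length]
        return self.bases[start : start + length]


def reverse_complement(s: NucSeq) -> NucSeq:
    """Reverse complement of ``s``; identifier and topology are preserved."""
    return NucSeq(s.id, revcomp(s.bases), s.topology)


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` (A/C/G/T) lies in the expansion of IUPAC ``code``."""
    b = base.upper()
    c = code.upper()
    if b not in _CONCRETE:
        raise SequenceError(f"base must be one of A/C/G/T, got {base!r}")
    try:
        return b in IUPAC[c]
    except KeyError:
        raise SequenceError(f"invalid IUPAC code {code!r}") from None


@dataclass(frozen=True)
class DegeneratePattern:
    """An IUPAC-coded motif such as ``YTAATKV`` or a recognition site.

    Matching is case-insensitive and per-position: a window of concrete
    bases matches iff every base lies in the expansion of the code at
    that position.
    """

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        code = self.code.upper()
        if not code:
            raise SequenceError("empty pattern")
        bad = sorted(set(code) - set(IUPAC))
        if bad:
            raise SequenceError(f"pattern {self.code!r}: invalid IUPAC codes {bad}")
        object.__setattr__(self, "code", code)
        if not self.label:
            object.__setattr__(self, "label", code)

    def __len__(self) -> int:
        return len(self.code)

    @property
    def expansion_size(self) -> int:
        n = 1
        for c in self.code:
            n *= len(IUPAC[c])
        return n

    def expansions(self, limit: int = 1 << 16) -> list[str]:
        """Every concrete sequence matching the pattern (guarded by ``limit``)."""
        if self.expansion_size > limit:
            raise SequenceError(
                f"pattern {self.code} expands to {self.expansion_size} sequences (> {limit})"
            )
        return ["".join(p) for p in _iproduct(*(sorted(IUPAC[c]) for c in self.code))]

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(revcomp(self.code), self.label)

    def regex(self) -> "re.Pattern[str]":
        """Compiled overlapping-match regex (one hit per start position)."""
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
            for c in self.code
        )
        return re.compile(f"(?=({body}))")

    def matches_text(self, text: str) -> bool:
        """Per-position check of a concrete window of the same length."""
        if len(text) != len(self.code):
            return False
        return all(iupac_match(b, c) for b, c in zip(text.upper(), self.code))


_FEATURE_KINDS = ("promoter", "CDS", "UTR_polyA", "enhancer", "spacer", "site", "misc")


@dataclass
class Feature:
    """An annotated interval on a construct, 1-based inclusive.

    On a circular map a feature spanning the origin has ``start > end``
    and is serialised to GenBank as ``join(start..N,1..end)``.
    """

    label: str
    kind: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in _FEATURE_KINDS:
            raise SequenceError(f"feature kind {self.kind!r} not one of {_FEATURE_KINDS}")
        if self.strand not in ("+", "-"):
            raise SequenceError(f"feature strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise SequenceError(f"feature {self.label!r}: positions are 1-based (>= 1)")

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def length(self, seq_len: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if seq_len is None:
            raise SequenceError("origin-spanning feature length needs the sequence length")
        return (seq_len - self.start + 1) + self.end


@dataclass
class ConstructMap:
    """A sequence plus its ordered feature annotations (a vector map)."""

    seq: NucSeq
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.seq)
        for f in self.features:
            if f.start > n or f.end > n:
                raise SequenceError(
                    f"feature {f.label!r} ({f.start}..{f.end}) outside sequence of length {n}"
                )
            if f.wraps_origin and not self.seq.is_circular:
                raise SequenceError(
                    f"feature {f.label!r} wraps the origin but the sequence is linear"
                )

    def feature_seq(self, f: Feature) -> str:
        """Strand-aware sequence of a feature (5'->3' on its own strand)."""
        if f.wraps_origin:
            top = self.seq.bases[f.start - 1 :] + self.seq.bases[: f.end]
        else:
            top = self.seq.bases[f.start - 1 : f.end]
        return top if f.strand == "+" else revcomp(top)

    def by_label(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def by_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


def circularly_equal(a: Union[NucSeq, str], b: Union[NucSeq, str]) -> bool:
    """True iff two sequences are identical up to choice of circular origin."""
    sa, sb = str(a), str(b)
    return len(sa) == len(sb) and (sa in sb + sb if sa else sb == "")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[NucSeq]:
    """Read a multi-record FASTA; lowercase is normalised, non-DNA rejects."""
    seqs: list[NucSeq] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            seqs.append(NucSeq(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise SequenceError(f"{path}, record {i + 1} ({rec.id!r}): {exc}") from None
    if not seqs:
        raise SequenceError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Union[NucSeq, Iterable[NucSeq]], path) -> None:
    """Write one or more sequences as 60-column-wrapped FASTA."""
    if isinstance(seqs, NucSeq):
        seqs = [seqs]
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"promoter": "promoter", "CDS": "CDS"}
_GB_TO_KIND = {"promoter": "promoter", "CDS": "CDS"}


def _to_seqrecord(cm: ConstructMap) -> SeqRecord:
    n = len(cm.seq)
    rec = SeqRecord(Seq(cm.seq.bases), id=cm.seq.id, name=cm.seq.id[:16] or "construct",
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = cm.seq.topology
    for f in cm.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, n, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        key = _KIND_TO_GB.get(f.kind, "misc_feature")
        quals = {"label": [f.label]}
        if key == "misc_feature":
            quals["note"] = [f"kind:{f.kind}"]
        rec.features.append(SeqFeature(loc, type=key, qualifiers=quals))
    return rec


def _from_seqrecord(rec: SeqRecord, source: str = "<genbank>") -> ConstructMap:
    topology = rec.annotations.get("topology", "linear")
    try:
        seq = NucSeq(rec.id or rec.name, str(rec.seq), topology)
    except SequenceError as exc:
        raise SequenceError(f"{source} ({rec.id!r}): {exc}") from None
    n = len(seq)
    feats: list[Feature] = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        label = (sf.qualifiers.get("label") or sf.qualifiers.get("gene") or ["feature"])[0]
        kind = _GB_TO_KIND.get(sf.type, "misc")
        for note in sf.qualifiers.get("note", []):
            if note.startswith("kind:"):
                kind = note[5:]
        strand = "-" if sf.location.strand == -1 else "+"
        parts = list(sf.location.parts)
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        else:
            start, end = int(sf.location.start) + 1, int(sf.location.end)
        feats.append(Feature(label, kind, start, end, strand))
    return ConstructMap(seq, feats)


def write_genbank(cm: ConstructMap, path) -> None:
    SeqIO.write([_to_seqrecord(cm)], str(path), "genbank")


def genbank_to_string(cm: ConstructMap) -> str:
    buf = StringIO()
    SeqIO.write([_to_seqrecord(cm)], buf, "genbank")
    return buf.getvalue()


def read_genbank(path) -> ConstructMap:
    if hasattr(path, "read"):
        records = list(SeqIO.parse(path, "genbank"))
        source = "<stream>"
    else:
        records = list(SeqIO.parse(str(path), "genbank"))
        source = str(path)
    if len(records) != 1:
        raise SequenceError(f"{source}: expected exactly one GenBank record, found {len(records)}")
    return _from_seqrecord(records[0], source)
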