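"""In-silico molecular cloning.

Models the restriction/ligation arithmetic the dual-reporter vectors were
actually built with: digestion with explicit cut-offset chemistry,
ligation that joins only compatible end overhangs and tracks whether a
junction scar is re-cuttable (the BamHI x BglII scar, for instance, is
cut by neither parent enzyme), PCR with tailed and degenerate primers,
and seamless homology-arm (In-Fusion-style) assembly.

Fragment convention
-------------------
A :class:`SeqFragment` stores the *top-strand span between top-strand cut
positions*.  End chemistry (the single-stranded overhang read 5'->3' on
its protruding strand, plus its polarity) is carried separately, so the
sum of fragment body lengths over a digest always equals the substrate
length with every overhang counted exactly once, and ligation is plain
body concatenation once end compatibility has been checked.  Two sticky
ends are compatible when they have the same polarity and their overhang
texts are reverse complements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .enzymes import ENZYMES, RestrictionEnzyme, get_enzyme
from .seqcore import (
    ConstructMap,
    DegeneratePattern,
    Feature,
    IUPAC,
    NucSeq,
    SequenceError,
    revcomp,
)

__all__ = [
    "End",
    "BLUNT",
    "SeqFragment",
    "JunctionReport",
    "LigationResult",
    "Primer",
    "DigestError",
    "LigationError",
    "AmplificationError",
    "AssemblyError",
    "digest",
    "ligate",
    "simulate_pcr",
    "infusion_assemble",
    "ends_compatible",
]


class DigestError(SequenceError):
    pass


class LigationError(SequenceError):
    pass


class AmplificationError(SequenceError):
    pass


class AssemblyError(SequenceError):
    pass


@dataclass(frozen=True)
class End:
    """One fragment terminus: overhang text (5'->3' on the protruding
    strand; empty when blunt) and polarity ('5p', '3p' or 'blunt')."""

    overhang: str = ""
    polarity: str = "blunt"

    def __post_init__(self) -> None:
        if self.polarity not in ("5p", "3p", "blunt"):
            raise SequenceError(f"bad end polarity {self.polarity!r}")
        if self.polarity == "blunt" and self.overhang:
            raise SequenceError("blunt ends carry no overhang text")
        if len(self.overhang) > 8:
            raise SequenceError("overhangs longer than 8 nt are not modelled")


BLUNT = End()


def ends_compatible(a: End, b: End) -> bool:
    """Can a fragment whose *right* end is ``a`` ligate to one whose *left*
    end is ``b``?  Blunt joins blunt; sticky ends need equal polarity and
    reverse-complementary overhangs."""
    if a.polarity != b.polarity:
        return False
    if a.polarity == "blunt":
        return True
    return a.overhang == revcomp(b.overhang)


@dataclass(frozen=True)
class SeqFragment:
    """A double-stranded fragment, stored as its top-strand body span."""

    body: str
    left_end: End = BLUNT
    right_end: End = BLUNT
    id: str = "fragment"
    circular: bool = False
    source_span: tuple[int, int] | None = None  # 0-based [start, end) on the substrate
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.body) - set("ACGT"):
            raise SequenceError(f"fragment {self.id!r}: body must be concrete DNA")

    def __len__(self) -> int:
        return len(self.body)


@dataclass(frozen=True)
class JunctionReport:
    """A ligation junction: its position and which enzymes re-cut the scar."""

    index: int
    position: int  # 1-based position of the first base 3' of the joint
    scar: str  # top-strand window centred on the joint
    recut_by: tuple[str, ...]


@dataclass(frozen=True)
class LigationResult:
    construct: ConstructMap
    junctions: tuple[JunctionReport, ...]


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def _substrate_of(c) -> NucSeq:
    if isinstance(c, ConstructMap):
        return c.seq
    if isinstance(c, NucSeq):
        return c
    raise SequenceError(f"cannot digest a {type(c).__name__}")


def _cut_events(bases: str, circular: bool, enzymes: list[RestrictionEnzyme]):
    """Distinct cut events as (top_cut, overhang_delta, enzyme name).

    ``overhang_delta = bottom_cut - top_cut`` (positive: 5' overhang).
    Recognition occurrences on the bottom strand cut with mirrored
    offsets; palindromic sites produce the same event on both strands and
    are deduplicated.  If two enzymes happen to cut at the same top-strand
    position (overlapping sites), the event of the first enzyme in the
    argument order wins -- double-strand DNA cannot be severed twice at
    one phosphodiester bond.
    """
    n = len(bases)
    events: dict[int, tuple[int, str]] = {}
    for enz in enzymes:
        m = len(enz.recognition)
        if m > n:
            continue
        text = bases + bases[: m - 1] if circular else bases
        delta = enz.cut_bottom - enz.cut_top
        for match in enz.recognition.regex().finditer(text):
            p = match.start()
            if p >= n:
                continue
            t = p + enz.cut_top
            events.setdefault((t % n) if circular else t, (delta, enz.name))
        rc = enz.recognition.reverse_complement()
        for match in rc.regex().finditer(text):
            p = match.start()
            if p >= n:
                continue
            t = p + m - enz.cut_bottom
            events.setdefault((t % n) if circular else t, (delta, enz.name))
    return sorted((t, d, name) for t, (d, name) in events.items())


def _arc(bases: str, start: int, end: int, circular: bool) -> str:
    """Top-strand text of [start, end); wraps when circular and end <= start."""
    n = len(bases)
    if circular:
        start %= n
        end %= n
        if end > start:
            return bases[start:end]
        return bases[start:] + bases[:end]
    return bases[start:end]


def _event_ends(bases: str, circular: bool, t: int, delta: int) -> tuple[End, End]:
    """(right end of the upstream fragment, left end of the downstream one)."""
    if delta == 0:
        return BLUNT, BLUNT
    if delta > 0:  # 5' overhang: ss text lies downstream of the top cut
        o = _arc(bases, t, t + delta, circular)
        return End(revcomp(o), "5p"), End(o, "5p")
    o = _arc(bases, t + delta, t, circular)  # 3' overhang: ss text upstream
    return End(o, "3p"), End(revcomp(o), "3p")


def digest(c, enzymes) -> list[SeqFragment]:
    """Cut a construct (or bare sequence) with one or more enzymes.

    Every recognition occurrence on either strand is cut, including across
    the origin of circular substrates.  A circular substrate with *k* cuts
    yields *k* linear fragments, a linear one *k + 1*; fragments come back
    in top-strand order with correct end chemistry.  With no occurrence at
    all the substrate is returned uncut, flagged with a warning.
    """
    sub = _substrate_of(c)
    enzymes = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]
    if not enzymes:
        raise DigestError("no enzymes given")
    bases, circular = sub.bases, sub.is_circular
    events = _cut_events(bases, circular, enzymes)
    if not events:
        names = ", ".join(e.name for e in enzymes)
        return [SeqFragment(
            body=bases, id=f"{sub.id}.uncut", circular=circular,
            source_span=(0, len(bases)),
            warnings=(f"no recognition site for {names} in {sub.id!r}; substrate returned uncut",),
        )]

    frags: list[SeqFragment] = []
    n = len(bases)
    if circular:
        for i, (t, d, _name) in enumerate(events):
            t2, d2, _ = events[(i + 1) % len(events)]
            _, left = _event_ends(bases, circular, t, d)
            right, _ = _event_ends(bases, circular, t2, d2)
            body = _arc(bases, t, t2 if len(events) > 1 else t + n, circular)
            if len(events) == 1:
                body = bases[t:] + bases[:t]
            frags.append(SeqFragment(body, left, right, f"{sub.id}.f{i + 1}",
                                     source_span=(t, t2)))
    else:
        cuts = [(0, None)] + [(t, d) for t, d, _ in events] + [(n, None)]
        for i in range(len(cuts) - 1):
            t, d = cuts[i]
            t2, d2 = cuts[i + 1]
            left = BLUNT if d is None else _event_ends(bases, circular, t, d)[1]
            right = BLUNT if d2 is None else _event_ends(bases, circular, t2, d2)[0]
            frags.append(SeqFragment(bases[t:t2], left, right, f"{sub.id}.f{i + 1}",
                                     source_span=(t, t2)))
    return frags


# ---------------------------------------------------------------------------
# Ligation
# ---------------------------------------------------------------------------

def _junction_recut(seq: NucSeq, boundary: int, enzymes) -> tuple[str, ...]:
    """Names of enzymes whose recognition site spans ``boundary`` (0-based
    joint between base boundary-1 and base boundary)."""
    names = []
    n = len(seq)
    for enz in enzymes:
        m = len(enz.recognition)
        spanning = False
        for patt in (enz.recognition, enz.recognition.reverse_complement()):
            text = seq.bases + seq.bases[: m - 1] if seq.is_circular else seq.bases
            for match in patt.regex().finditer(text):
                p = match.start()
                if p >= n:
                    continue
                b = boundary if boundary > p else boundary + (n if seq.is_circular else 0)
                if p < b < p + m:
                    spanning = True
                    break
            if spanning:
                break
        if spanning:
            names.append(enz.name)
    return tuple(names)


def ligate(fragments: list[SeqFragment], circularize: bool,
           enzymes=(), id: str = "ligation") -> LigationResult:
    """Join fragments in the given order, checking end compatibility.

    The output annotates every junction and reports, for each enzyme in
    ``enzymes``, whether the junction scar regenerates a cuttable site.
    Incompatible adjacent ends fail naming the junction.  When not
    circularising, any sticky outer termini are left as they are (the
    construct records the top strand only).
    """
    if not fragments:
        raise LigationError("nothing to ligate")
    for f in fragments:
        if f.circular:
            raise LigationError(f"fragment {f.id!r} is circular; digest it first")
    enzymes = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]

    n_j = len(fragments) if circularize else len(fragments) - 1
    for i in range(n_j):
        a = fragments[i].right_end
        b = fragments[(i + 1) % len(fragments)].left_end
        if not ends_compatible(a, b):
            raise LigationError(
                f"junction {i + 1} ({fragments[i].id} -> "
                f"{fragments[(i + 1) % len(fragments)].id}): incompatible ends "
                f"{a.polarity}:{a.overhang or '-'} x {b.polarity}:{b.overhang or '-'}"
            )

    body = "".join(f.body for f in fragments)
    topology = "circular" if circularize else "linear"
    seq = NucSeq(id, body, topology)
    n = len(body)

    junctions: list[JunctionReport] = []
    features: list[Feature] = []
    offset = 0
    boundaries = []
    for f in fragments[:-1]:
        offset += len(f.body)
        boundaries.append(offset)
    if circularize:
        boundaries.append(0)
    for k, b in enumerate(boundaries):
        lo, hi = b - 7, b + 7
        scar = _arc(body, lo % n if seq.is_circular else max(lo, 0),
                    hi % n if seq.is_circular else min(hi, n), seq.is_circular) \
            if seq.is_circular else body[max(lo, 0): min(hi, n)]
        junctions.append(JunctionReport(
            index=k + 1,
            position=(b % n) + 1,
            scar=scar,
            recut_by=_junction_recut(seq, b, enzymes),
        ))
        start = b if b >= 1 else n  # 2-bp feature spanning the joint
        features.append(Feature(f"junction_{k + 1}", "misc", start, (b % n) + 1, "+"))
    cm = ConstructMap(seq, features)
    return LigationResult(cm, tuple(junctions))


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate, possibly tailed) oligo.

    The 3'-terminal ``min_anneal`` bases define the annealing footprint;
    everything 5' of that is tail and is carried into the product whether
    or not it matches the template.
    """

    name: str
    full: str
    min_anneal: int = 15

    def __post_init__(self) -> None:
        full = self.full.upper()
        bad = sorted(set(full) - set(IUPAC))
        if bad:
            raise SequenceError(f"primer {self.name!r}: invalid characters {bad}")
        if self.min_anneal < 1:
            raise SequenceError("min_anneal must be >= 1")
        if len(full) < self.min_anneal:
            raise SequenceError(
                f"primer {self.name!r}: length {len(full)} < min_anneal {self.min_anneal}"
            )
        object.__setattr__(self, "full", full)

    @property
    def anneal_region(self) -> str:
        return self.full[-self.min_anneal:]

    @property
    def tail(self) -> str:
        return self.full[: -self.min_anneal]


def _resolve_degenerate(text: str) -> str:
    """Concrete stand-in for a degenerate stretch: alphabetically first
    expansion at every position (documented, deterministic choice)."""
    return "".join(min(IUPAC[c]) for c in text)


def _unique_footprint(template: str, window: DegeneratePattern, what: str) -> int:
    hits = [m.start() for m in window.regex().finditer(template)]
    if not hits:
        raise AmplificationError(f"no amplicon: {what} has no annealing site")
    if len(hits) > 1:
        raise AmplificationError(
            f"ambiguous amplicon: {what} anneals at {len(hits)} positions "
            f"{[h + 1 for h in hits]}"
        )
    return hits[0]


def simulate_pcr(template: NucSeq, fwd: Primer, rev: Primer) -> SeqFragment:
    """Amplify ``template`` with a forward and a reverse primer.

    Each primer's 3'-terminal annealing window must match its strand at
    exactly one position (IUPAC-aware), with the forward footprint 5' of
    the reverse one.  The product is the full forward primer, the template
    between the footprints, and the reverse complement of the full reverse
    primer; degenerate annealed positions resolve to the template base,
    degenerate tail positions to a fixed documented expansion.  Ends are
    blunt.
    """
    tpl = template.bases
    fw = DegeneratePattern(fwd.anneal_region, fwd.name)
    rv_rc = DegeneratePattern(revcomp(rev.anneal_region), rev.name)
    f = _unique_footprint(tpl, fw, f"forward primer {fwd.name!r}")
    q = _unique_footprint(tpl, rv_rc, f"reverse primer {rev.name!r}")
    mf, mr = len(fw), len(rv_rc)
    if f + mf > q:
        raise AmplificationError(
            "no amplicon: forward footprint does not lie 5' of the reverse footprint"
        )
    fwd_resolved = _resolve_degenerate(fwd.tail) + tpl[f : f + mf]
    rev_resolved = _resolve_degenerate(rev.tail) + revcomp(tpl[q : q + mr])
    product = fwd_resolved + tpl[f + mf : q] + revcomp(rev_resolved)
    return SeqFragment(product, BLUNT, BLUNT, id=f"{template.id}.amplicon",
                       source_span=(f, q + mr))


# ---------------------------------------------------------------------------
# Homology-arm assembly
# ---------------------------------------------------------------------------

def infusion_assemble(linear_vector: SeqFragment, insert: SeqFragment,
                      arm_len: int = 15) -> ConstructMap:
    """Seamless assembly of an insert into a linearised vector via terminal
    homology arms of ``arm_len`` bp (exact match required).

    Each homologous region appears once in the product; the assembled
    circle has length ``len(vector) + len(insert) - 2 * arm_len``.
    """
    v, i = linear_vector.body, insert.body
    if linear_vector.circular:
        raise AssemblyError("vector must be linearised before assembly")
    if len(v) < arm_len or len(i) < 2 * arm_len:
        raise AssemblyError("fragments shorter than the homology arms")
    if i[:arm_len] != v[-arm_len:]:
        raise AssemblyError(
            f"5' homology arm mismatch: insert starts {i[:arm_len]}, "
            f"vector ends {v[-arm_len:]}"
        )
    if i[-arm_len:] != v[:arm_len]:
        raise AssemblyError(
            f"3' homology arm mismatch: insert ends {i[-arm_len:]}, "
            f"vector starts {v[:arm_len]}"
        )
    seq = NucSeq(f"{linear_vector.id}+{insert.id}", v + i[arm_len : len(i) - arm_len],
                 "circular")
    return ConstructMap(seq, [])
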