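"""Detection and elimination of forbidden motifs and restriction sites.

A designed spacer must not carry transcription-factor binding motifs
(Hox-like ``YTAATKV``, Abd-B ``TTTAT``) nor recognition sites for the
enzymes used as single cutters in the destination vector.  This module
scans for IUPAC-degenerate patterns on one or both strands (including
across the origin of circular sequences) and edits matches away:

* ``fixed_replacement`` rules swap the whole matched window for a stated
  same-length replacement (e.g. ``TTTAT -> TTGGG``);
* ``substitute_min`` rules change single bases, preferring the
  non-complementary transversion at the left-most fully-constrained
  pattern position, backtracking deterministically if an edit would
  create a fresh forbidden match.

Coding sequences get a separate mode in which every edit is a synonymous
codon substitution, so the translated protein is conserved exactly.

Every scrub returns a :class:`ScrubReport` listing each edit, and
:func:`verify_clean` re-certifies the result by an independent
brute-force search (expansion enumeration + plain substring search)
that shares no code with the scanning path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .mutagenesis import NC_TRANSVERSION, TRANSITION
from .seqcore import (
    IUPAC,
    DegeneratePattern,
    NucSeq,
    SequenceError,
    complement,
    revcomp,
)

__all__ = [
    "ForbiddenRule",
    "Edit",
    "ScrubReport",
    "ScrubError",
    "find_matches",
    "scrub_noncoding",
    "scrub_coding_synonymous",
    "verify_clean",
    "motif_rule",
    "fixed_rule",
    "site_rule",
    "hox_spacer_rules",
    "translate",
]

_COMPLEMENT1 = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScrubError(SequenceError):
    """Scrub failure (non-convergence or an undestroyable site)."""

    def __init__(self, message: str, report: "ScrubReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class ForbiddenRule:
    """A pattern that must not occur, and how to remove it when it does."""

    pattern: DegeneratePattern
    strand_policy: str = "both"  # "given" (top strand only) or "both"
    action: str = "substitute_min"  # or "fixed_replacement"
    replacement: str | None = None

    def __post_init__(self) -> None:
        if self.strand_policy not in ("given", "both"):
            raise SequenceError(f"strand_policy must be 'given' or 'both', got {self.strand_policy!r}")
        if self.action not in ("substitute_min", "fixed_replacement"):
            raise SequenceError(f"unknown action {self.action!r}")
        if self.action == "fixed_replacement":
            if not self.replacement or len(self.replacement) != len(self.pattern):
                raise SequenceError(
                    f"rule {self.label}: fixed replacement must match pattern length"
                )
            object.__setattr__(self, "replacement", self.replacement.upper())
            if set(self.replacement) - set("ACGT"):
                raise SequenceError(f"rule {self.label}: replacement must be concrete DNA")
        elif self.replacement is not None:
            raise SequenceError("substitute_min rules carry no replacement text")

    @property
    def label(self) -> str:
        return self.pattern.label


def motif_rule(code: str, label: str = "", strand_policy: str = "both") -> ForbiddenRule:
    return ForbiddenRule(DegeneratePattern(code, label), strand_policy, "substitute_min")


def fixed_rule(code: str, replacement: str, label: str = "",
               strand_policy: str = "both") -> ForbiddenRule:
    return ForbiddenRule(DegeneratePattern(code, label), strand_policy,
                         "fixed_replacement", replacement)


def site_rule(enzyme_name: str, strand_policy: str = "both") -> ForbiddenRule:
    from .enzymes import get_enzyme  # local import; enzymes module is tiny

    return ForbiddenRule(get_enzyme(enzyme_name).recognition, strand_policy, "substitute_min")


def hox_spacer_rules(fixed_tttat: bool = False,
                     site_names: tuple[str, ...] = ()) -> list[ForbiddenRule]:
    """The spacer-design rule set: Hox-like motifs plus optional cutter sites.

    ``fixed_tttat=True`` uses the explicit TTTAT -> TTGGG replacement used
    for the Abd-B motif in one spacer generation; otherwise TTTAT is removed
    by minimal substitution like YTAATKV.
    """
    rules = [motif_rule("YTAATKV", "Hox-like")]
    if fixed_tttat:
        rules.append(fixed_rule("TTTAT", "TTGGG", "AbdB"))
    else:
        rules.append(motif_rule("TTTAT", "AbdB"))
    rules.extend(site_rule(n) for n in site_names)
    return rules


@dataclass(frozen=True)
class Edit:
    """One recorded change: 1-based position, old and new text, rule, strand."""

    position: int
    old: str
    new: str
    rule: str
    strand: str = "+"

    def to_dict(self) -> dict:
        return {"position": self.position, "from": self.old, "to": self.new,
                "rule": self.rule, "strand": self.strand}


@dataclass
class ScrubReport:
    """Auditable record of a scrub run."""

    edits: list[Edit] = field(default_factory=list)
    residual: list[tuple[str, int, str]] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "edits": [e.to_dict() for e in self.edits],
            "residual": [{"rule": r, "position": p, "strand": s} for r, p, s in self.residual],
            "iterations": self.iterations,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Match:
    rule_index: int
    start: int  # 0-based top-strand start
    length: int
    strand: str


def _scan_starts(text: str, pattern: DegeneratePattern) -> list[int]:
    return [m.start() for m in pattern.regex().finditer(text)]


def _scan_text(bases: str, circular: bool, pattern: DegeneratePattern,
               strand_policy: str) -> list[tuple[int, str]]:
    m = len(pattern)
    n = len(bases)
    if m > n:
        return []
    text = bases + bases[: m - 1] if circular else bases
    hits = [(s, "+") for s in _scan_starts(text, pattern) if s < n]
    if strand_policy == "both":
        rc = pattern.reverse_complement()
        hits += [(s, "-") for s in _scan_starts(text, rc) if s < n]
    return sorted(hits)


def find_matches(s: NucSeq, p: DegeneratePattern,
                 strand_policy: str = "given") -> list[tuple[int, str]]:
    """All (1-based position, strand) windows of ``s`` matching ``p``.

    Overlapping matches are all reported; circular sequences are scanned
    across the origin; a palindromic window under ``strand_policy='both'``
    is reported once per strand at the same top-strand coordinate.
    """
    return [(start + 1, strand)
            for start, strand in _scan_text(s.bases, s.is_circular, p, strand_policy)]


def _all_matches(bases: str, circular: bool, rules: list[ForbiddenRule]) -> list[_Match]:
    out: list[_Match] = []
    for i, rule in enumerate(rules):
        for start, strand in _scan_text(bases, circular, rule.pattern, rule.strand_policy):
            out.append(_Match(i, start, len(rule.pattern), strand))
    return out


def _read_window(chars: list[str], start: int, length: int, circular: bool) -> str:
    n = len(chars)
    if start + length <= n:
        return "".join(chars[start : start + length])
    if not circular:
        raise SequenceError("window beyond end of linear sequence")
    return "".join(chars[start:]) + "".join(chars[: (start + length) % n])


def _write_window(chars: list[str], start: int, text: str, circular: bool) -> None:
    n = len(chars)
    for k, c in enumerate(text):
        chars[(start + k) % n if circular else start + k] = c


# ---------------------------------------------------------------------------
# Noncoding scrub
# ---------------------------------------------------------------------------

def _matches_overlapping(chars: list[str], circular: bool,
                         rules: list[ForbiddenRule], pos: int) -> set[_Match]:
    """Matches (any rule) whose window covers the 0-based position ``pos``.

    Only a neighbourhood of ``pos`` is scanned, which keeps edit validation
    cheap on long sequences: a match overlapping ``pos`` must start within
    ``maxlen - 1`` bases of it.
    """
    n = len(chars)
    maxlen = max(len(r.pattern) for r in rules)
    lo = pos - maxlen + 1
    hi = pos + maxlen  # exclusive end of the furthest window
    if circular:
        text = "".join(chars[(lo + k) % n] for k in range(hi - lo))
        offset = lo % n
    else:
        lo = max(lo, 0)
        hi = min(hi, n)
        text = "".join(chars[lo:hi])
        offset = lo
    out: set[_Match] = set()
    for i, rule in enumerate(rules):
        patterns = [rule.pattern]
        if rule.strand_policy == "both":
            patterns.append(rule.pattern.reverse_complement())
        for pi, patt in enumerate(patterns):
            strand = "+" if pi == 0 else "-"
            for s in _scan_starts(text, patt):
                start = (offset + s) % n if circular else offset + s
                covers = ((pos - start) % n) < len(patt) if circular \
                    else start <= pos < start + len(patt)
                if covers:
                    out.add(_Match(i, start, len(patt), strand))
    return out


def _min_substitution(chars: list[str], circular: bool, target: _Match,
                      rules: list[ForbiddenRule], before: set[_Match]) -> Edit:
    """Pick and apply the deterministic single-base edit destroying ``target``.

    Candidate positions are pattern positions with a fully-constrained
    (non-degenerate) code first, then degenerate ones, each left to right
    in pattern orientation; candidate bases are tried in the fixed order
    non-complementary transversion, complement (the other transversion),
    transition.  The first candidate whose edit kills the target without
    creating any new forbidden match anywhere wins; if every candidate
    creates collateral matches, the first target-killing edit is taken and
    the outer fix-point iteration deals with the fallout.
    """
    rule = rules[target.rule_index]
    code = rule.pattern.code
    m = target.length
    window = _read_window(chars, target.start, m, circular)
    frame = window if target.strand == "+" else revcomp(window)

    ordered = [j for j in range(m) if len(IUPAC[code[j]]) == 1]
    ordered += [j for j in range(m) if 1 < len(IUPAC[code[j]]) < 4]
    fallback: tuple[int, str] | None = None
    n = len(chars)

    for j in ordered:
        b = frame[j]
        for nb in (NC_TRANSVERSION[b], _COMPLEMENT1[b], TRANSITION[b]):
            if nb in IUPAC[code[j]]:
                continue  # would still satisfy the pattern at this position
            if target.strand == "+":
                off, newbase = j, nb
            else:
                off, newbase = m - 1 - j, _COMPLEMENT1[nb]
            pos = (target.start + off) % n if circular else target.start + off
            old = chars[pos]
            local_before = {m for m in before
                            if (((pos - m.start) % n) < m.length if circular
                                else m.start <= pos < m.start + m.length)}
            chars[pos] = newbase
            after = _matches_overlapping(chars, circular, rules, pos)
            if target not in after and after <= local_before - {target}:
                return Edit(pos + 1, old, newbase, rule.label, target.strand)
            if target not in after and fallback is None:
                fallback = (pos, newbase)
            chars[pos] = old

    if fallback is None:
        raise ScrubError(
            f"rule {rule.label}: no single-base substitution can destroy the match at "
            f"position {target.start + 1} (pattern too degenerate)"
        )
    pos, newbase = fallback
    old = chars[pos]
    chars[pos] = newbase
    return Edit(pos + 1, old, newbase, rule.label, target.strand)


def scrub_noncoding(s: NucSeq, rules: list[ForbiddenRule],
                    iteration_cap: int | None = None) -> tuple[NucSeq, ScrubReport]:
    """Iteratively remove every rule match from ``s`` (noncoding: free edits).

    Fixed-replacement rules take priority over minimal-substitution rules
    (an explicit replacement is honoured verbatim); within a priority class
    the left-most match is fixed first and the sequence rescanned.  Length
    is always preserved.  Non-convergence within the iteration cap (default
    ``10 * len(s)``) raises :class:`ScrubError` carrying the report.
    """
    if not rules:
        raise SequenceError("scrub_noncoding needs a non-empty rule set")
    for rule in rules:
        if rule.action == "fixed_replacement":
            probe = NucSeq("_probe", rule.replacement)
            for other in rules:
                if find_matches(probe, other.pattern, other.strand_policy):
                    raise SequenceError(
                        f"replacement {rule.replacement} for rule {rule.label} itself "
                        f"matches rule {other.label}"
                    )
    chars = list(s.bases)
    circular = s.is_circular
    n = len(chars)
    cap = iteration_cap if iteration_cap is not None else max(100, 10 * len(s))
    report = ScrubReport()

    def _overlaps(m: _Match, pos: int) -> bool:
        return ((pos - m.start) % n) < m.length if circular \
            else m.start <= pos < m.start + m.length

    def _priority(m: _Match):
        return (0 if rules[m.rule_index].action == "fixed_replacement" else 1,
                m.start, m.strand, m.rule_index)

    # One full scan up front; afterwards an edit can only create or destroy
    # matches overlapping the edited bases, so the match set is maintained
    # incrementally and re-certified by a final full rescan.
    matches = set(_all_matches("".join(chars), circular, rules))
    while matches:
        if report.iterations >= cap:
            report.residual = sorted(
                (rules[m.rule_index].label, m.start + 1, m.strand) for m in matches
            )
            raise ScrubError(
                f"scrub of {s.id!r} did not converge within {cap} iterations "
                f"({len(matches)} matches remain; conflicting rules?)", report
            )
        report.iterations += 1
        target = min(matches, key=_priority)
        rule = rules[target.rule_index]
        if rule.action == "fixed_replacement":
            old = _read_window(chars, target.start, target.length, circular)
            new = rule.replacement if target.strand == "+" else revcomp(rule.replacement)
            _write_window(chars, target.start, new, circular)
            report.edits.append(Edit(target.start + 1, old, new, rule.label, target.strand))
            touched = [(target.start + k) % n if circular else target.start + k
                       for k in range(target.length)]
        else:
            edit = _min_substitution(chars, circular, target, rules, matches)
            report.edits.append(edit)
            touched = [edit.position - 1]
        matches = {m for m in matches if not any(_overlaps(m, p) for p in touched)}
        for p in touched:
            matches |= _matches_overlapping(chars, circular, rules, p)

    residual = _all_matches("".join(chars), circular, rules)
    if residual:  # defensive: incremental bookkeeping must agree with a full scan
        report.residual = sorted(
            (rules[m.rule_index].label, m.start + 1, m.strand) for m in residual
        )
        raise ScrubError(f"scrub of {s.id!r} left residual matches", report)
    report.converged = True
    out = s.with_bases("".join(chars))
    report.residual = []
    return out, report


# ---------------------------------------------------------------------------
# Coding (synonymous) scrub
# ---------------------------------------------------------------------------

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()


def translate(bases: str) -> str:
    """Standard-code translation of an in-frame stretch ('*' for stops)."""
    if len(bases) % 3:
        raise SequenceError(f"length {len(bases)} is not a multiple of 3")
    return "".join(CODON_TO_AA[bases[i : i + 3]] for i in range(0, len(bases), 3))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scrub_coding_synonymous(cds: NucSeq, frame_start: int,
                            site: DegeneratePattern,
                            strand_policy: str = "both") -> tuple[NucSeq, ScrubReport]:
    """Destroy every occurrence of ``site`` inside a CDS without changing
    the encoded protein.

    ``frame_start`` is the 1-based position of the first base of codon 1.
    Edits are whole-codon synonymous substitutions ordered by minimal
    Hamming distance (a single base change whenever possible), then
    left-most codon, then lexicographically smallest codon.  If no
    synonymous substitution can break a match (e.g. a site spelled
    entirely by Met/Trp codons) the scrub fails explicitly.
    """
    if cds.is_circular:
        raise SequenceError("coding scrub expects a linear CDS")
    f0 = frame_start - 1
    if not 0 <= f0 < len(cds):
        raise SequenceError(f"frame_start {frame_start} outside sequence")
    n_codons = (len(cds) - f0) // 3
    region_end = f0 + 3 * n_codons
    chars = list(cds.bases)
    report = ScrubReport()
    cap = max(10, len(cds))

    def region_matches() -> list[tuple[int, str]]:
        hits = _scan_text("".join(chars), False, site, strand_policy)
        return [(st, strand) for st, strand in hits
                if f0 <= st and st + len(site) <= region_end]

    while True:
        matches = region_matches()
        if not matches:
            report.converged = True
            break
        if report.iterations >= cap:
            report.residual = [(site.label, st + 1, strand) for st, strand in matches]
            raise ScrubError(f"coding scrub of {cds.id!r} did not converge", report)
        report.iterations += 1
        start, strand = matches[0]
        end = start + len(site)
        first_codon = (start - f0) // 3
        last_codon = (end - 1 - f0) // 3

        candidates: list[tuple[int, int, str]] = []
        for ci in range(first_codon, last_codon + 1):
            cpos = f0 + 3 * ci
            old_codon = "".join(chars[cpos : cpos + 3])
            for alt in _SYNONYMS[CODON_TO_AA[old_codon]]:
                if alt != old_codon:
                    candidates.append((_hamming(old_codon, alt), ci, alt))
        candidates.sort()

        applied = False
        fallback: tuple[int, str] | None = None
        for _, ci, alt in candidates:
            cpos = f0 + 3 * ci
            old_codon = "".join(chars[cpos : cpos + 3])
            chars[cpos : cpos + 3] = list(alt)
            after = set(region_matches())
            if (start, strand) not in after and after <= set(matches) - {(start, strand)}:
                report.edits.append(Edit(cpos + 1, old_codon, alt, site.label, strand))
                applied = True
                break
            if (start, strand) not in after and fallback is None:
                fallback = (ci, alt)
            chars[cpos : cpos + 3] = list(old_codon)
        if not applied and fallback is not None:
            ci, alt = fallback
            cpos = f0 + 3 * ci
            old_codon = "".join(chars[cpos : cpos + 3])
            chars[cpos : cpos + 3] = list(alt)
            report.edits.append(Edit(cpos + 1, old_codon, alt, site.label, strand))
            applied = True
        if not applied:
            report.residual = [(site.label, start + 1, strand)]
            raise ScrubError(
                f"no synonymous substitution destroys the {site.label} site at "
                f"position {start + 1} of {cds.id!r}", report
            )

    return cds.with_bases("".join(chars)), report


# ---------------------------------------------------------------------------
# Independent certification
# ---------------------------------------------------------------------------

def _find_all_substring(text: str, sub: str) -> list[int]:
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def verify_clean(s: NucSeq, rules: list[ForbiddenRule]) -> tuple[bool, list[tuple[str, int, str]]]:
    """Certify zero residual matches by brute force.

    Deliberately independent of :func:`find_matches`: each pattern is
    expanded to its full set of concrete sequences and located with plain
    substring search (both strands, across the circular seam).  Returns
    ``(clean, hits)`` with hits as (rule label, 1-based position, strand).
    """
    n = len(s)
    hits: set[tuple[str, int, str]] = set()
    for rule in rules:
        m = len(rule.pattern)
        if m > n:
            continue
        text = s.bases + s.bases[: m - 1] if s.is_circular else s.bases
        for exp in rule.pattern.expansions():
            for pos in _find_all_substring(text, exp):
                if pos < n:
                    hits.add((rule.label, pos + 1, "+"))
        if rule.strand_policy == "both":
            for exp in rule.pattern.expansions():
                rc = revcomp(exp)
                for pos in _find_all_substring(text, rc):
                    if pos < n:
                        hits.add((rule.label, pos + 1, "-"))
    return (not hits, sorted(hits))
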