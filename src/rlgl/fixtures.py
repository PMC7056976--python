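"""Deterministic synthetic fixtures.

Real inputs to this toolkit are genomic donor DNA, enhancers, promoters
and reporter ORFs.  For testing (and for the worked demo design) this
module generates stand-ins with controlled properties: random DNA of a
given length and GC fraction, planted IUPAC motif / restriction-site
instances at known non-overlapping positions, and reading-frame-clean
random ORFs.  Everything is driven by one integer seed through a single
:class:`random.Random` stream per spec, so any failure reproduces
exactly.

Planted instances are written *after* the background is laid down, so
they survive generation verbatim; chance background occurrences of the
same patterns are permitted but enumerated in the manifest's background
audit, letting scrub tests account for every match.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .designer import DesignConfig, DesignReport, Part, assemble_reporter_vector, design_spacer
from .enzymes import ENZYMES, get_enzyme
from .motifscrub import (
    CODON_TO_AA,
    ForbiddenRule,
    find_matches,
    hox_spacer_rules,
    scrub_coding_synonymous,
    scrub_noncoding,
    site_rule,
    verify_clean,
)
from .mutagenesis import NC_TRANSVERSION
from .seqcore import IUPAC, DegeneratePattern, NucSeq, SequenceError, revcomp

__all__ = [
    "FixtureError",
    "PlantSpec",
    "CdsSpec",
    "FixtureSpec",
    "PlantedInstance",
    "FixtureManifest",
    "generate_fixture",
    "random_dna",
    "random_orf",
    "demo_reporter_config",
    "demo_reporter_design",
    "DEMO_CUTTERS",
]


class FixtureError(SequenceError):
    pass


def random_dna(rng: random.Random, length: int, gc_fraction: float = 0.5) -> str:
    """Random DNA with the requested expected GC fraction."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise FixtureError("gc_fraction must lie in [0, 1]")
    return "".join(
        rng.choice("GC") if rng.random() < gc_fraction else rng.choice("AT")
        for _ in range(length)
    )


_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*" and c != "ATG")


def random_orf(rng: random.Random, n_codons: int) -> str:
    """ATG + (n_codons - 2) random sense codons + TAA stop."""
    if n_codons < 2:
        raise FixtureError("an ORF needs at least start and stop codons")
    middle = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    return "ATG" + middle + "TAA"


@dataclass(frozen=True)
class PlantSpec:
    """Plant ``count`` instances of a pattern (or named enzyme site)."""

    pattern: str  # IUPAC code, or a bundled enzyme name
    count: int
    strand: str = "+"

    def resolve(self) -> DegeneratePattern:
        if self.pattern in ENZYMES:
            return ENZYMES[self.pattern].recognition
        return DegeneratePattern(self.pattern)


@dataclass(frozen=True)
class CdsSpec:
    """Overwrite a region with an in-frame ORF (1-based start)."""

    start: int
    n_codons: int


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    length: int
    gc_fraction: float = 0.5
    planted: tuple[PlantSpec, ...] = ()
    cds_segments: tuple[CdsSpec, ...] = ()


@dataclass(frozen=True)
class PlantedInstance:
    label: str
    position: int  # 1-based top-strand start of the planted window
    strand: str
    realized: str  # top-strand text actually written


@dataclass
class FixtureManifest:
    planted: list[PlantedInstance] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)  # (start, end) 1-based
    background: dict[str, list[tuple[int, str]]] = field(default_factory=dict)


def generate_fixture(spec: FixtureSpec) -> tuple[NucSeq, FixtureManifest]:
    """Build the fixture sequence and its full manifest.

    Deterministic in ``spec``; planted windows never overlap each other or
    a CDS segment; infeasible planting fails explicitly.  The background
    audit lists *every* match (planted or chance) of each planted pattern
    on both strands.
    """
    rng = random.Random(spec.seed)
    chars = list(random_dna(rng, spec.length, spec.gc_fraction))
    manifest = FixtureManifest()
    occupied: list[tuple[int, int]] = []  # 0-based half-open

    for cds in spec.cds_segments:
        start0 = cds.start - 1
        end0 = start0 + 3 * cds.n_codons
        if start0 < 0 or end0 > spec.length:
            raise FixtureError(f"CDS segment {cds} outside fixture of length {spec.length}")
        if any(s < end0 and start0 < e for s, e in occupied):
            raise FixtureError(f"CDS segment {cds} overlaps another segment")
        chars[start0:end0] = list(random_orf(rng, cds.n_codons))
        occupied.append((start0, end0))
        manifest.cds.append((cds.start, end0))

    for plant in spec.planted:
        patt = plant.resolve()
        m = len(patt)
        if m > spec.length:
            raise FixtureError(f"pattern {patt.label} longer than the fixture")
        if plant.strand not in ("+", "-"):
            raise FixtureError("plant strand must be '+' or '-'")
        for _ in range(plant.count):
            placed = False
            for _attempt in range(200 * max(plant.count, 1)):
                pos = rng.randrange(0, spec.length - m + 1)
                if any(s < pos + m and pos < e for s, e in occupied):
                    continue
                realized = "".join(rng.choice(sorted(IUPAC[c])) for c in patt.code)
                top = realized if plant.strand == "+" else revcomp(realized)
                chars[pos : pos + m] = list(top)
                occupied.append((pos, pos + m))
                manifest.planted.append(
                    PlantedInstance(patt.label, pos + 1, plant.strand, top)
                )
                placed = True
                break
            if not placed:
                raise FixtureError(
                    f"could not place {plant.count} non-overlapping instances of "
                    f"{patt.label} in {spec.length} bp"
                )

    seq = NucSeq(f"fixture_seed{spec.seed}", "".join(chars))
    for plant in spec.planted:
        patt = plant.resolve()
        if patt.label not in manifest.background:
            manifest.background[patt.label] = find_matches(seq, patt, "both")
    return seq, manifest


# ---------------------------------------------------------------------------
# Demo dual-reporter design (synthetic parts throughout)
# ---------------------------------------------------------------------------

#: Enzymes used as junction punctuation / declared single cutters in the demo.
DEMO_CUTTERS = ("FseI", "StuI", "BamHI", "BglII", "AscI", "SbfI", "XhoI", "AgeI", "SpeI")

#: Junction punctuation of the canonical divergent layout, parts being
#: distal polyA | distal CDS | distal promoter | spacer | enhancer |
#: proximal promoter | proximal CDS | proximal polyA (closing junction bare).
DEMO_JUNCTIONS = (
    ("FseI",), ("StuI",), ("BamHI",), ("BglII", "AscI"), ("SbfI", "XhoI"),
    ("AgeI",), ("SpeI",),
)


def _clean_noncoding_part(rng: random.Random, label: str, kind: str, length: int,
                          rules: list[ForbiddenRule], orientation: str = "+") -> Part:
    seq = NucSeq(label, random_dna(rng, length))
    seq, _ = scrub_noncoding(seq, rules)
    return Part(label, kind, seq, orientation)


def _clean_cds_part(rng: random.Random, label: str, n_codons: int,
                    site_rules: list[ForbiddenRule], orientation: str = "+") -> Part:
    seq = NucSeq(label, random_orf(rng, n_codons))
    for _round in range(10):
        for rule in site_rules:
            seq, _ = scrub_coding_synonymous(seq, 1, rule.pattern)
        if verify_clean(seq, site_rules)[0]:
            return Part(label, "CDS", seq, orientation)
    raise FixtureError(f"could not clear all sites from synthetic CDS {label!r}")


def _synonymous_point_fix(seq: NucSeq, local0: int) -> NucSeq | None:
    """Change the base at ``local0`` of an in-frame ORF synonymously, if possible."""
    ci = local0 // 3
    cpos = 3 * ci
    old = seq.bases[cpos : cpos + 3]
    off = local0 - cpos
    for alt in sorted(c for c, aa in CODON_TO_AA.items() if aa == CODON_TO_AA[old]):
        if alt != old and alt[off] != old[off]:
            return seq.with_bases(seq.bases[:cpos] + alt + seq.bases[cpos + 3 :])
    return None


def demo_reporter_config(seed: int, spacer_kb: int = 2) -> DesignConfig:
    """A fully synthetic, verification-clean dual-reporter design.

    Parts are random stand-ins (scrubbed of all declared cutter sites;
    spacer generated by :func:`design_spacer`), laid out in the divergent
    dual-reporter architecture.  After assembly, any chance restriction
    site straddling a part/junction boundary is removed by a point edit
    in the adjacent part (synonymous when the part is a CDS) and the
    design re-verified, so the returned config always passes all checks.
    """
    rng = random.Random(seed)
    site_rules = [site_rule(n) for n in DEMO_CUTTERS]
    rules = hox_spacer_rules(fixed_tttat=False, site_names=DEMO_CUTTERS)

    donor = NucSeq("donor_intron_sim", random_dna(rng, max(1000, spacer_kb * 1000)))
    spacer, spacer_report = design_spacer(donor, spacer_kb, rules, rng.randrange(2 ** 31))

    parts = [
        _clean_noncoding_part(rng, "distal_polyA", "UTR_polyA", 150, rules, "-"),
        _clean_cds_part(rng, "distal_reporter", 240, site_rules, "-"),
        _clean_noncoding_part(rng, "distal_promoter", "promoter", 250, rules, "-"),
        Part("spacer", "spacer", spacer, "+"),
        _clean_noncoding_part(rng, "enhancer", "enhancer", 632, rules, "+"),
        _clean_noncoding_part(rng, "proximal_promoter", "promoter", 250, rules, "+"),
        _clean_cds_part(rng, "proximal_reporter", 240, site_rules, "+"),
        _clean_noncoding_part(rng, "proximal_polyA", "UTR_polyA", 150, rules, "+"),
    ]
    cfg = DesignConfig(
        vector_id=f"demo_rlgl{spacer_kb}",
        parts=parts,
        junction_sites=[list(j) for j in DEMO_JUNCTIONS],
        unique_cutters=list(DEMO_CUTTERS),
        forbidden_rules=rules,
        provenance={
            "seed": seed,
            "spacer_recipe": "tandem" if spacer_kb in (1, 2) else "scramble-odd" if spacer_kb else "none",
            "spacer_edits": len(spacer_report.edits),
        },
    )
    return _fix_boundary_sites(cfg)


def _fix_boundary_sites(cfg: DesignConfig, max_rounds: int = 40) -> DesignConfig:
    """Remove chance cutter occurrences created at part boundaries."""
    for _round in range(max_rounds):
        report = assemble_reporter_vector(cfg)
        extras = _extra_cutter_positions(report)
        if not extras:
            return cfg
        cfg = _edit_away(cfg, report, extras[0])
    raise FixtureError("boundary-site cleanup did not converge")


def _extra_cutter_positions(report: DesignReport) -> list[tuple[str, int]]:
    cm = report.assembled
    intended = {}
    for f in cm.by_kind("site"):
        name = f.label.split("_site")[0]
        intended.setdefault(name, set()).add(f.start)
    extras = []
    for check in report.checks:
        if check.name.startswith("unique_cutter_") and not check.passed:
            name = check.name[len("unique_cutter_"):]
            enz = get_enzyme(name)
            for pos, _ in find_matches(cm.seq, enz.recognition, "both"):
                if pos not in intended.get(name, set()):
                    extras.append((name, pos))
    return sorted(set(extras), key=lambda x: x[1])


def _edit_away(cfg: DesignConfig, report: DesignReport,
               extra: tuple[str, int]) -> DesignConfig:
    name, pos = extra
    cm = report.assembled
    m = len(get_enzyme(name).recognition)
    n = len(cm.seq)
    window = [(pos - 1 + k) % n for k in range(m)]  # 0-based map positions
    site_spans = [(f.start - 1, f.end) for f in cm.by_kind("site")]
    for p0 in window:
        if any(s <= p0 < e for s, e in site_spans):
            continue
        for f in cm.features:
            if f.kind == "site" or not (f.start - 1 <= p0 < f.end):
                continue
            part = cfg.part(f.label)
            local0 = (p0 - (f.start - 1)) if f.strand == "+" else (f.end - 1 - p0)
            if part.kind == "CDS":
                fixed = _synonymous_point_fix(part.seq, local0)
                if fixed is None:
                    continue
            else:
                b = part.seq.bases[local0]
                fixed = part.seq.with_bases(
                    part.seq.bases[:local0] + NC_TRANSVERSION[b] + part.seq.bases[local0 + 1 :]
                )
                if part.kind == "spacer":
                    fixed, _ = scrub_noncoding(fixed, cfg.forbidden_rules)
            return cfg.with_part(f.label, Part(f.label, part.kind, fixed, part.orientation))
    raise FixtureError(f"cannot edit away extra {name} site at position {pos}")


def demo_reporter_design(seed: int, spacer_kb: int = 2) -> DesignReport:
    """Convenience: build the demo config and return its verified report."""
    return assemble_reporter_vector(demo_reporter_config(seed, spacer_kb))
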