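"""Design pipelines composing the mutagenesis, scrubbing and cloning layers.

Covers the three construct-level jobs:

* :func:`design_spacer` -- generate a regulatory-neutral spacer of 0, 1,
  2, 4 or 8 kb from donor DNA.  The short spacers (1-2 kb) are built as
  odd/even-phased tandem duplicates of a donor unit; the long ones
  (4-8 kb) scramble the donor composition, transversion-mutate odd
  positions and then scrub.  Either way the result is certified free of
  Hox-like binding motifs and of every restriction site declared as a
  single cutter in the destination vector.

* :func:`assemble_reporter_vector` -- concatenate an ordered parts list
  with declared restriction-site punctuation into a circular, annotated
  dual-reporter map (divergent architecture: distal polyA <- distal CDS
  <- distal promoter -- spacer -- enhancer -- proximal promoter ->
  proximal CDS -> polyA), then verify it.

* :func:`verify_design` -- the design checks: declared single cutters
  occur exactly once on the circular map, generated spacers re-certify
  clean, both reporter CDSs translate without internal stops, and each
  promoter sits 5' of its reporter in the annotated orientation.

Part swaps are modelled two ways that must agree: restriction
digestion + ligation on the assembled map, or re-assembly from an edited
config (see :func:`replace_feature_by_digestion`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clonesim import LigationResult, SeqFragment, digest, ligate
from .enzymes import ENZYMES, get_enzyme
from .motifscrub import (
    ForbiddenRule,
    ScrubReport,
    find_matches,
    fixed_rule,
    motif_rule,
    site_rule,
    translate,
    scrub_noncoding,
    verify_clean,
)
from .mutagenesis import MutationSpec, apply_mutation_pattern, build_tandem_spacer, scramble_composition
from .seqcore import ConstructMap, Feature, NucSeq, SequenceError, read_fasta

__all__ = [
    "Part",
    "DesignConfig",
    "CheckResult",
    "DesignReport",
    "DesignError",
    "design_spacer",
    "assemble_reporter_vector",
    "verify_design",
    "remove_feature_by_digestion",
    "replace_feature_by_digestion",
    "load_config",
]

SPACER_TARGETS_KB = (0, 1, 2, 4, 8)


class DesignError(SequenceError):
    pass


@dataclass(frozen=True)
class Part:
    """One building block of the vector, in final-map orientation."""

    label: str
    kind: str  # a Feature kind: promoter / CDS / UTR_polyA / enhancer / spacer / misc
    seq: NucSeq
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise DesignError(f"part {self.label!r}: orientation must be '+' or '-'")
        if len(self.seq) == 0:
            raise DesignError(f"part {self.label!r}: empty sequence")


@dataclass
class DesignConfig:
    """Everything needed to assemble and verify a dual-reporter vector."""

    vector_id: str
    parts: list[Part]
    junction_sites: list[list[str]]  # per inter-part junction, enzyme names (may be empty)
    unique_cutters: list[str]
    forbidden_rules: list[ForbiddenRule] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.parts]
        if len(set(labels)) != len(labels):
            raise DesignError("part labels must be unique")
        if len(self.junction_sites) != max(len(self.parts) - 1, 0):
            raise DesignError(
                f"need {len(self.parts) - 1} junction entries for {len(self.parts)} parts, "
                f"got {len(self.junction_sites)}"
            )
        for names in self.junction_sites:
            for n in names:
                get_enzyme(n)
        for n in self.unique_cutters:
            get_enzyme(n)

    def part(self, label: str) -> Part:
        for p in self.parts:
            if p.label == label:
                return p
        raise KeyError(label)

    def with_part(self, label: str, new: Part) -> "DesignConfig":
        parts = [new if p.label == label else p for p in self.parts]
        return DesignConfig(self.vector_id, parts, self.junction_sites,
                            self.unique_cutters, self.forbidden_rules, dict(self.provenance))

    def without_part(self, label: str, drop_junctions: tuple[int, ...] = ()) -> "DesignConfig":
        """Remove a part and the junction entries at the given indices."""
        idx = [i for i, p in enumerate(self.parts) if p.label == label]
        if not idx:
            raise KeyError(label)
        parts = [p for p in self.parts if p.label != label]
        junctions = [j for i, j in enumerate(self.junction_sites) if i not in drop_junctions]
        junctions = junctions[: max(len(parts) - 1, 0)]
        return DesignConfig(self.vector_id, parts, junctions,
                            self.unique_cutters, self.forbidden_rules, dict(self.provenance))


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    evidence: str

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "evidence": self.evidence}


@dataclass
class DesignReport:
    assembled: ConstructMap
    checks: list[CheckResult]
    provenance: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_checks(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def to_dict(self) -> dict:
        return {
            "vector_id": self.assembled.seq.id,
            "length": len(self.assembled.seq),
            "topology": self.assembled.seq.topology,
            "passed": self.passed,
            "checks": [c.to_dict() for c in self.checks],
            "features": [
                {"label": f.label, "kind": f.kind, "start": f.start, "end": f.end,
                 "strand": f.strand}
                for f in self.assembled.features
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Spacer design
# ---------------------------------------------------------------------------

def design_spacer(source: NucSeq, target_kb: int, rules: list[ForbiddenRule],
                  seed: int) -> tuple[NucSeq, ScrubReport]:
    """Generate a clean spacer of ``target_kb`` kb from donor sequence.

    * 0 kb: the empty spacer (trivially clean).
    * 1-2 kb: tandem-duplicate recipe -- the first ``target/2`` bp of the
      donor are duplicated, the copies transversion-mutated at odd and
      even positions respectively, then scrubbed.
    * 4-8 kb: scramble recipe -- the first ``target`` bp of the donor
      have their composition scrambled (seeded), odd positions
      transversion-mutated, then scrubbed.

    The returned spacer always passes :func:`verify_clean` against the
    full rule set; scrub non-convergence propagates.
    """
    if target_kb not in SPACER_TARGETS_KB:
        raise DesignError(f"target_kb must be one of {SPACER_TARGETS_KB}, got {target_kb}")
    out_id = f"{source.id}_spacer{target_kb}kb"
    if target_kb == 0:
        report = ScrubReport(converged=True)
        return NucSeq(out_id, ""), report
    target = target_kb * 1000
    if target_kb in (1, 2):
        unit_len = target // 2
        if len(source) < unit_len:
            raise DesignError(
                f"donor {source.id!r} has {len(source)} bp; tandem recipe needs {unit_len}"
            )
        unit = NucSeq(source.id, source.bases[:unit_len])
        staged = build_tandem_spacer(unit)
    else:
        if len(source) < target:
            raise DesignError(
                f"donor {source.id!r} has {len(source)} bp; scramble recipe needs {target}"
            )
        staged = scramble_composition(NucSeq(source.id, source.bases[:target]), seed)
        staged = apply_mutation_pattern(staged, MutationSpec("odd"))
    clean, report = scrub_noncoding(staged, rules)
    clean = NucSeq(out_id, clean.bases)
    ok, hits = verify_clean(clean, rules)
    if not ok:  # contract cross-check; unreachable when scrub converged
        raise DesignError(f"spacer {out_id}: residual matches after scrub: {hits[:5]}")
    return clean, report


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_reporter_vector(cfg: DesignConfig) -> DesignReport:
    """Concatenate parts and site punctuation into a verified circular map."""
    chunks: list[str] = []
    features: list[Feature] = []
    pos = 0
    for i, part in enumerate(cfg.parts):
        text = part.seq.bases if part.orientation == "+" else _revcomp(part.seq.bases)
        chunks.append(text)
        features.append(Feature(part.label, part.kind, pos + 1, pos + len(text),
                                part.orientation))
        pos += len(text)
        if i < len(cfg.parts) - 1:
            for name in cfg.junction_sites[i]:
                site = get_enzyme(name).site
                chunks.append(site)
                features.append(Feature(f"{name}_site_j{i + 1}", "site",
                                        pos + 1, pos + len(site)))
                pos += len(site)
    seq = NucSeq(cfg.vector_id, "".join(chunks), "circular")
    cm = ConstructMap(seq, features)
    checks = verify_design(cm, cfg)
    return DesignReport(cm, checks, dict(cfg.provenance))


def _revcomp(text: str) -> str:
    from .seqcore import revcomp

    return revcomp(text)


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def _between(lo: int, hi: int, f: Feature) -> bool:
    return f.start > lo and f.end < hi


def verify_design(cm: ConstructMap, cfg: DesignConfig) -> list[CheckResult]:
    """Run the full design check battery; failures are report entries."""
    checks: list[CheckResult] = []

    for name in cfg.unique_cutters:
        enz = get_enzyme(name)
        starts = sorted({p for p, _ in find_matches(cm.seq, enz.recognition, "both")})
        checks.append(CheckResult(
            f"unique_cutter_{name}", len(starts) == 1,
            f"{name} recognition occurrences at positions {starts}",
        ))

    for f in cm.by_kind("spacer"):
        sub = NucSeq(f.label, cm.feature_seq(f))
        if len(sub) == 0:
            checks.append(CheckResult(f"clean_{f.label}", True, "empty spacer"))
            continue
        ok, hits = verify_clean(sub, cfg.forbidden_rules)
        checks.append(CheckResult(
            f"clean_{f.label}", ok,
            "no residual forbidden matches" if ok else f"residual matches: {hits[:5]}",
        ))

    cds_feats = cm.by_kind("CDS")
    for f in cds_feats:
        text = cm.feature_seq(f)
        if len(text) % 3:
            checks.append(CheckResult(f"cds_translates_{f.label}", False,
                                      f"length {len(text)} not a multiple of 3"))
            continue
        if not text.startswith("ATG"):
            checks.append(CheckResult(f"cds_translates_{f.label}", False,
                                      "does not start with ATG"))
            continue
        aa = translate(text)
        internal = aa[:-1]
        if "*" in internal:
            checks.append(CheckResult(
                f"cds_translates_{f.label}", False,
                f"internal stop at codon {internal.index('*') + 1}",
            ))
        else:
            checks.append(CheckResult(f"cds_translates_{f.label}", True,
                                      f"{len(aa)} codons, no internal stop"))

    promoters = cm.by_kind("promoter")
    for f in cds_feats:
        same = [p for p in promoters if p.strand == f.strand]
        if f.strand == "+":
            ups = [p for p in same if p.end < f.start]
            best = max(ups, key=lambda p: p.end) if ups else None
            gap = (best.end, f.start) if best else None
        else:
            ups = [p for p in same if p.start > f.end]
            best = min(ups, key=lambda p: p.start) if ups else None
            gap = (f.end, best.start) if best else None
        ok = best is not None and not any(
            _between(gap[0], gap[1], other) for other in cds_feats if other is not f
        )
        checks.append(CheckResult(
            f"promoter_upstream_of_{f.label}", ok,
            f"promoter {best.label!r} at {best.start}..{best.end} ({best.strand})"
            if best else "no same-strand promoter upstream",
        ))

    return checks


# ---------------------------------------------------------------------------
# Restriction-based part surgery on assembled maps
# ---------------------------------------------------------------------------

def _span_contains(span: tuple[int, int], pos0: int, n: int) -> bool:
    s, e = span
    if s < e:
        return s <= pos0 < e
    return pos0 >= s or pos0 < e  # wraps the origin


def _split_backbone(cm: ConstructMap, feature_label: str,
                    enzyme_names: tuple[str, str]) -> tuple[SeqFragment, SeqFragment]:
    """Digest with two enzymes and separate (backbone, segment-with-feature)."""
    frags = digest(cm, list(enzyme_names))
    if len(frags) != 2:
        raise DesignError(
            f"expected 2 fragments from {'+'.join(enzyme_names)} digest, got {len(frags)}"
        )
    f = cm.by_label(feature_label)
    pos0 = f.start - 1
    n = len(cm.seq)
    inside = [fr for fr in frags if _span_contains(fr.source_span, pos0, n)]
    outside = [fr for fr in frags if not _span_contains(fr.source_span, pos0, n)]
    if len(inside) != 1:
        raise DesignError(f"feature {feature_label!r} not resolvable to one fragment")
    return outside[0], inside[0]


def remove_feature_by_digestion(cm: ConstructMap, feature_label: str,
                                enzyme_names: tuple[str, str],
                                report_enzymes=()) -> LigationResult:
    """Excise the fragment carrying a feature and re-ligate the backbone.

    Mirrors the 0 kb-spacer construction: cut at the two flanking sites,
    discard the feature-carrying fragment, self-ligate.  The junction
    report records whether either enzyme can re-cut the scar.
    """
    backbone, _ = _split_backbone(cm, feature_label, enzyme_names)
    return ligate([backbone], circularize=True,
                  enzymes=list(report_enzymes) or list(enzyme_names),
                  id=f"{cm.seq.id}_wo_{feature_label}")


def replace_feature_by_digestion(cm: ConstructMap, feature_label: str,
                                 insert: SeqFragment,
                                 enzyme_names: tuple[str, str],
                                 report_enzymes=()) -> LigationResult:
    """Swap the fragment carrying a feature for a new insert fragment."""
    backbone, _ = _split_backbone(cm, feature_label, enzyme_names)
    return ligate([backbone, insert], circularize=True,
                  enzymes=list(report_enzymes) or list(enzyme_names),
                  id=f"{cm.seq.id}_swap_{feature_label}")


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _rule_from_dict(d: dict) -> ForbiddenRule:
    if "site" in d:
        return site_rule(d["site"], d.get("strands", "both"))
    action = d.get("action", "substitute_min")
    if action in ("fixed", "fixed_replacement"):
        return fixed_rule(d["pattern"], d["replacement"], d.get("label", ""),
                          d.get("strands", "both"))
    return motif_rule(d["pattern"], d.get("label", ""), d.get("strands", "both"))


def load_config(path) -> DesignConfig:
    """Load a design config from YAML.

    Schema (version 1)::

        vector_id: my_vector
        parts:
          - {label: enhancer, kind: enhancer, seq: ACGT..., orientation: "+"}
          - {label: cds, kind: CDS, fasta: cds.fa, orientation: "-"}
        junctions: [[AscI], [SbfI, XhoI], ...]   # len(parts) - 1 entries
        unique_cutters: [AscI, SbfI]
        forbidden:
          - {pattern: YTAATKV, label: Hox-like}
          - {pattern: TTTAT, label: AbdB, action: fixed, replacement: TTGGG}
          - {site: NheI}
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    for key in ("vector_id", "parts", "junctions"):
        if key not in raw:
            raise DesignError(f"{path}: config is missing required key {key!r}")
    parts = []
    for d in raw["parts"]:
        if "seq" in d:
            seq = NucSeq(d["label"], d["seq"])
        elif "fasta" in d:
            seq = read_fasta(path.parent / d["fasta"])[0]
        else:
            raise DesignError(f"{path}: part {d.get('label')!r} needs 'seq' or 'fasta'")
        parts.append(Part(d["label"], d.get("kind", "misc"), seq, d.get("orientation", "+")))
    return DesignConfig(
        vector_id=raw["vector_id"],
        parts=parts,
        junction_sites=[list(j) for j in raw["junctions"]],
        unique_cutters=list(raw.get("unique_cutters", [])),
        forbidden_rules=[_rule_from_dict(d) for d in raw.get("forbidden", [])],
        provenance={"config": str(path), "schema_version": raw.get("version", 1)},
    )
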