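# Methods

This note documents the models and conventions behind `rlgl`, the
parameters that matter, what the synthetic fixtures do and do not
emulate, and the design choices made where more than one reasonable
convention exists.

## The mutation operator

All neutralising mutagenesis uses the *non-complementary transversion*.
Each nucleotide has two transversion partners (purine↔pyrimidine); one
of the two is the Watson–Crick complement. Excluding the complement
leaves exactly one choice per base, so the operator is a forced map

    A → C,  C → A,  G → T,  T → G

and an involution (applying it twice is the identity). Two consequences
are load-bearing and tested: a sequence mutated "every other bp" at odd
positions and a copy mutated at even positions disagree at **every**
aligned position (wherever one copy kept the original base the other
changed it), so a tandem-duplicate spacer contains no intact repeat that
could recombine or retain binding sites; and a scanning-series mutant
differs from its parent at exactly its block, since the map never fixes
a base.

**Phase.** "Every other bp" does not specify whether position 1 or
position 2 is hit first. The default phase mutates 1-based odd
positions; both phases are exposed (`MutationSpec("odd"/"even")`,
`every_other(phase=...)`) rather than guessed, and the tandem-duplicate
recipe uses odd for copy 1 and even for copy 2 by construction.

**Scrambling.** Composition scrambling is a Fisher–Yates shuffle from
Python's `random.Random` seeded with an explicit integer recorded in
design provenance. It preserves the base multiset (hence GC content)
exactly and destroys all positional information.

**Scanning series.** A parent of length *n* with block length *b*
yields ⌈n/b⌉ mutants tiling the parent 5′→3′; a short terminal block is
emitted as its own mutant rather than merged, keeping every mutant's
footprint interpretable on its own.

## Motif scrubbing

Forbidden patterns are IUPAC-degenerate (`YTAATKV` for Hox-like sites,
`TTTAT` for Abd-B, concrete recognition sequences for enzymes). A
window matches if every base lies in the per-position expansion set;
overlapping matches are all reported, and circular sequences are
scanned across the origin so no site can hide at the seam.

**Strand policy.** Transcription-factor binding is strand-agnostic and
restriction sites are double-stranded entities, so both motif and site
rules default to both-strand scanning. The policy is per-rule
configuration, not hard-coded.

**Edit policy.** Two actions exist. `fixed_replacement` substitutes the
whole matched window with a same-length stated replacement (`TTTAT →
TTGGG`; on a minus-strand match the reverse complement of the
replacement is written at the plus-strand window). `substitute_min`
changes single bases deterministically: the left-most match is fixed
first; within a match, candidate positions are the pattern's
fully-constrained (non-degenerate) positions left-to-right, then the
degenerate ones; candidate bases are tried in the fixed order
non-complementary transversion, complement, transition. An edit is
accepted only if it destroys the target match and creates no new match
of any rule; if every candidate has collateral damage, the first
target-destroying edit is taken and the fix-point iteration continues.
Fixed-replacement rules take priority over substitution rules when both
match (an explicit replacement is honoured verbatim). The iteration cap
is 10× the sequence length; hitting it raises an error carrying the
full report, which is the signature of mutually conflicting rules.

**Coding mode.** Inside a CDS, edits are whole-codon synonymous
substitutions under the standard genetic code, ordered by minimal
Hamming distance (single base change preferred), then left-most codon,
then lexicographically smallest codon — deterministic without assuming
any codon-usage preference. Translation is conserved codon-by-codon by
construction; a site whose every overlapping codon is Met/Trp (or whose
degenerate pattern absorbs all synonymous wiggle) fails explicitly.

**Certification.** `verify_clean` is deliberately a second
implementation: it expands each pattern to its full set of concrete
sequences and locates them with plain substring search on both strands.
Converged scrubs must pass it; the property suites assert the scanner
and the brute-force route agree match-for-match on random sequences.

## Cloning model

**Fragments.** A digest fragment stores the top-strand span between
adjacent top-strand cut positions; end chemistry (overhang text read
5′→3′ on the protruding strand, and 5′/3′/blunt polarity) is carried
separately. This makes two invariants structural: fragment body lengths
over a digest sum exactly to the substrate length (each overhang counted
once), and ligation is body concatenation after an end-compatibility
check (equal polarity, reverse-complementary overhangs).

**Digestion.** Cut offsets are bundled data (`data/enzymes.yaml`,
version 1) cross-checked in the test suite against the Biopython
restriction catalog rather than trusted as typed. Every recognition
occurrence on either strand is cut — complete digestion; partial
digests, star activity and methylation sensitivity are out of scope. A
circular substrate with *k* cuts yields *k* fragments, linear *k*+1.
If two enzymes' chance-overlapping sites would cut the same
phosphodiester position, one cut event is kept (first enzyme in
argument order): dsDNA cannot be severed twice at one bond.

**Ligation scars.** Each junction is annotated and scanned for every
configured enzyme's recognition sequence spanning the joint. Same-enzyme
religation regenerates the site (EcoRI×EcoRI → `GAATTC`); the
BamHI×BglII junction used for spacer excision yields `GGATCT`, cut by
neither enzyme — kept as a fixed regression test.

**PCR.** Annealing is exact IUPAC-compatible matching of the
3′-terminal `min_anneal` bases (default 15) — no mismatch tolerance and
no melting-temperature model, because the simulated primers are
exact-match designs. Zero or multiple footprints abort (`no amplicon` /
`ambiguous amplicon`): a silently wrong amplicon is worse than a
failure. Degenerate primer positions resolve to the template base in
the annealed footprint and to the alphabetically first expansion in
unannealed tails (an arbitrary but documented choice).

**Homology-arm assembly.** Seamless join with exact terminal arms,
default 15 bp; assembled length is vector + insert − 2×arm. Arm length
is a parameter since different kits use different homology lengths.

## Vector assembly and verification

A design config is an ordered parts list, per-junction restriction-site
punctuation (a junction may carry several sites, e.g. BglII+AscI between
spacer and enhancer), declared unique cutters, and the forbidden-rule
set. Assembly concatenates parts (reverse-complementing minus-strand
parts) and punctuation into a circular annotated map. The canonical
layout is the divergent dual-reporter architecture; it is expressed in
the config, not hard-coded, so variant layouts (promoter swaps,
enhancer-less controls) are config edits. Inter-part filler beyond the
punctuation sites defaults to empty — the tool does not invent sequence.

Verification checks: (1) each declared unique cutter has exactly one
recognition occurrence on the full circular map (both strands, window
dedup for palindromes); (2) spacer features re-certify clean against
the full rule set; (3) each CDS starts with ATG and translates without
internal stops; (4) each CDS has a same-strand promoter 5′ of it with no
other CDS in between. Failures are report entries with locating
evidence, not exceptions.

Part swaps are validated two ways that must agree exactly: restriction
digestion + ligation on the assembled map versus re-assembly from the
edited config (`tests` assert circular-rotation equality, since
religating a circle only moves the arbitrary origin).

## Synthetic fixtures and the demo design

Fixtures are random DNA of configurable length and GC fraction with
planted motif/site instances at recorded non-overlapping positions and
optional in-frame ORF segments; planting happens after background
generation so instances survive verbatim, and a background audit lists
*every* occurrence of each planted pattern so scrub tests can account
for chance background matches honestly. One `random.Random` stream per
fixture seed makes failures reproducible.

The demo dual-reporter design uses 150 bp polyA stand-ins, 250 bp
promoter stand-ins, 240-codon reporter ORFs, a 632 bp enhancer stand-in
and a 2 kb designed spacer — sizes chosen to match the magnitudes of
the real parts while keeping assembly and verification fast. After
assembly, any restriction site that arises by chance across a
part/junction boundary is removed by a single point edit in the
adjacent part (synonymous when the part is a CDS) and the design
re-verified; this mirrors what a designer does when an ectopic site
appears in a cloning plan.

What the fixtures do **not** emulate: real genomic base composition and
repeat structure, codon-usage bias of real reporter ORFs, functional
promoter/polyA sequence content, and any regulatory activity. Passing
tests therefore certify the combinatorial and biochemical bookkeeping —
coordinates, chemistry, translation, site accounting — not any
biological behaviour of designed constructs.

## Problem sizes in the test suite

The property suites run 10,000 random sequences through the mutation
operators; 200 fixtures of 10 kb (50 planted instances each) through
plant-then-scrub with independent re-certification; 60 random 200-codon
CDSs through coding scrub; 500 + 2,000-trial digest/ligate round trips;
and multi-seed assembly/verification fixed-point checks. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* No thermodynamics anywhere: primer annealing is exact matching,
  ligation is chemistry-only, assembly arms are exact.
* No position-weight-matrix motif scoring; forbidden motifs are hard
  IUPAC patterns.
* Enzyme table covers the 13 enzymes used in this vector family; other
  enzymes can be added to the YAML asset.
* Coding scrub edits one codon at a time; a (pathological) site
  destroyable only by simultaneous multi-codon edits is reported as a
  failure rather than searched exhaustively.
* GenBank I/O round-trips this package's own maps (LOCUS topology,
  promoter/CDS/misc_feature keys, origin-spanning joins); it is not a
  general-purpose GenBank dialect normaliser.
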