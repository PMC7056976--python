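# rlgl — construct design for dual fluorescent reporter transgenes

`rlgl` implements the DNA-design computations behind dual-reporter
("Red Light/Green Light"-style) transgene vectors used to study
enhancer–promoter specificity in *Drosophila*: an enhancer sits between
two fluorescent reporter genes, proximal to one promoter and displaced
from the other by a designed spacer of 1–8 kb, so that one transgene
simultaneously reads out proximal and long-distance activation.

The package is for people who design such constructs. It covers four
jobs that are error-prone to do by hand:

1. **Regulatory-neutral spacer DNA.** Spacers are derived from donor
   genomic sequence by *non-complementary transversions* — each base has
   two purine↔pyrimidine partners and one of them is its Watson–Crick
   complement, so excluding the complement forces the unique involution
   A→C, C→A, G→T, T→G. Recipes: odd/even-phased tandem duplication for
   1–2 kb spacers, and composition scrambling + odd-position
   transversions for 4–8 kb, followed in both cases by motif scrubbing.
2. **Motif/site scrubbing.** Hox-like binding motifs (IUPAC `YTAATKV`,
   and the Abd-B motif `TTTAT`) and restriction sites used as single
   cutters in the destination vector are detected on both strands
   (including across a plasmid's origin) and edited away, either by a
   fixed replacement (`TTTAT → TTGGG`) or by minimal deterministic
   substitutions. Inside reporter coding sequences the scrub is
   restricted to synonymous codon substitutions, so the protein is
   conserved exactly. Every scrub returns an auditable edit report and
   is re-certified by an independent brute-force scan.
3. **In-silico cloning.** Restriction digestion with real cut-offset
   chemistry (5′/3′ overhangs, blunt ends), ligation that accepts only
   compatible ends and reports whether each junction scar is re-cuttable
   (the BamHI×BglII scar `GGATCT`, used to excise spacers, is cut by
   neither parent enzyme), PCR with tailed and degenerate primers, and
   seamless 15 bp homology-arm assembly.
4. **Vector assembly and verification.** A parts-list config is
   assembled into an annotated circular GenBank map with the divergent
   dual-reporter architecture (distal polyA ← distal CDS ← distal
   promoter — spacer — enhancer — proximal promoter → proximal CDS →
   polyA) and checked: every declared single cutter occurs exactly once,
   spacers re-certify clean, both reporter CDSs translate without
   internal stops, and each promoter lies 5′ of its reporter.

## Worked example

Design a certified 2 kb spacer from 1 kb of donor sequence (here a
seeded random stand-in for intronic donor DNA):

```python
import random
from rlgl.seqcore import NucSeq
from rlgl.designer import design_spacer
from rlgl.motifscrub import hox_spacer_rules, verify_clean
from rlgl.fixtures import random_dna

rng = random.Random(7)
donor = NucSeq("bab1_intron_sim", random_dna(rng, 1000))
rules = hox_spacer_rules(site_names=("NheI", "SbfI", "SpeI", "SacII", "AgeI"))
spacer, report = design_spacer(donor, 2, rules, seed=7)
print(f"{spacer.id}: {len(spacer)} bp")
print(f"scrub edits: {len(report.edits)}  (converged={report.converged})")
for e in report.edits[:3]:
    print(f"  pos {e.position}: {e.old} -> {e.new}  [{e.rule}, {e.strand}]")
clean, hits = verify_clean(spacer, rules)
print(f"independent re-scan: clean={clean}, residual={len(hits)}")
```

prints

```
bab1_intron_sim_spacer2kb: 2000 bp
scrub edits: 8  (converged=True)
  pos 23: T -> G  [Hox-like, +]
  pos 96: T -> G  [AbdB, +]
  pos 759: A -> C  [AbdB, -]
independent re-scan: clean=True, residual=0
```

The donor's first kilobase was duplicated in tandem, the two copies
transversion-mutated at odd and even positions respectively (so the
copies disagree at every aligned position and no intact duplicate
remains), and the 8 residual Hox-like/Abd-B motif matches — on either
strand — were substituted away. `verify_clean` is an independent
expansion-and-substring search, not the scanner the scrub used.

The same machinery is available from the shell:

```sh
rlgl spacer tandem --unit donor.fasta --out spacer.fasta
rlgl scrub --rules rules.yaml --in spacer.fasta --out clean.fasta --report report.json
rlgl scan --block-len 50 --in enhancer.fasta --out scan_dir/   # scanning mutants
rlgl digest --enzymes BamHI,BglII --in vector.gb --out frags.json
rlgl design --config design.yaml --out vector.gb --report design.json
```

## Layout

```
src/rlgl/seqcore.py      DNA primitives, IUPAC semantics, FASTA/GenBank I/O
src/rlgl/mutagenesis.py  transversion operators, tandem/scrambled spacers, scanning series
src/rlgl/motifscrub.py   forbidden-motif detection and certified removal
src/rlgl/clonesim.py     digestion, ligation scars, PCR, homology-arm assembly
src/rlgl/designer.py     spacer recipes, vector assembly, design verification
src/rlgl/fixtures.py     deterministic synthetic inputs and the demo design
src/rlgl/cli.py          the `rlgl` command-line interface
docs/methods.md          models, conventions, parameter choices, limitations
```
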