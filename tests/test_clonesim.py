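"""Digestion chemistry, ligation scars, PCR, and homology-arm assembly."""

import random

import pytest

from rlgl.clonesim import (
    AmplificationError,
    AssemblyError,
    End,
    LigationError,
    Primer,
    SeqFragment,
    digest,
    ends_compatible,
    infusion_assemble,
    ligate,
    simulate_pcr,
)
from rlgl.enzymes import ENZYME_TABLE_VERSION, ENZYMES
from rlgl.seqcore import NucSeq, SequenceError, circularly_equal, revcomp


def _random_dna(seed, n):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _without_sites(text, names):
    for name in names:
        site = ENZYMES[name].site
        while site in text or revcomp(site) in text:
            text = text.replace(site, site[:-1] + "A").replace(revcomp(site), "A" + revcomp(site)[1:])
    return text


class TestEnzymeTable:
    def test_offsets_match_public_reference(self):
        # cross-check every bundled enzyme against Bio.Restriction (REBASE)
        from Bio import Restriction

        assert ENZYME_TABLE_VERSION == 1
        for name, enz in ENZYMES.items():
            ref = getattr(Restriction, name)
            assert enz.site == ref.site, name
            assert enz.cut_top == ref.fst5, name
            assert enz.cut_bottom == len(ref.site) + ref.fst3, name

    def test_overhang_chemistry_derivation(self):
        assert ENZYMES["EcoRI"].overhang_kind == "5p" and ENZYMES["EcoRI"].overhang_len == 4
        assert ENZYMES["SbfI"].overhang_kind == "3p" and ENZYMES["SbfI"].overhang_len == 4
        assert ENZYMES["StuI"].overhang_kind == "blunt" and ENZYMES["StuI"].overhang_len == 0


class TestDigest:
    def test_circular_single_ecorI_site(self):
        body = _without_sites(_random_dna(0, 94), ["EcoRI"])
        plasmid = NucSeq("p", body + "GAATTC", "circular")
        frags = digest(plasmid, ["EcoRI"])
        assert len(frags) == 1
        f = frags[0]
        assert len(f.body) == 100
        assert f.left_end == End("AATT", "5p") and f.right_end == End("AATT", "5p")

    def test_circular_single_stuI_site_is_blunt(self):
        body = _without_sites(_random_dna(1, 60), ["StuI"])
        plasmid = NucSeq("p", body + "AGGCCT", "circular")
        frags = digest(plasmid, ["StuI"])
        assert len(frags) == 1
        assert frags[0].left_end.polarity == "blunt" and frags[0].right_end.polarity == "blunt"

    def test_sbfI_leaves_three_prime_tgca_overhangs(self):
        body = _without_sites(_random_dna(2, 80), ["SbfI"])
        plasmid = NucSeq("p", body + "CCTGCAGG", "circular")
        f = digest(plasmid, ["SbfI"])[0]
        assert f.left_end == End("TGCA", "3p") and f.right_end == End("TGCA", "3p")

    def test_linear_two_bamhI_sites_conserves_length(self):
        mid = _without_sites(_random_dna(3, 20), ["BamHI"])
        outer = _without_sites(_random_dna(4, 14), ["BamHI"])
        seq = NucSeq("s", outer + "GGATCC" + mid + "GGATCC" + outer)
        assert len(seq) == 60
        frags = digest(seq, ["BamHI"])
        assert len(frags) == 3
        assert sum(len(f.body) for f in frags) == 60
        assert frags[0].left_end.polarity == "blunt"  # native linear terminus

    def test_no_site_returns_uncut_with_warning(self):
        seq = NucSeq("s", "ACGT" * 20, "circular")
        frags = digest(seq, ["NotI"])
        assert len(frags) == 1
        assert frags[0].warnings and "NotI" in frags[0].warnings[0]

    def test_site_spanning_circular_origin_is_cut(self):
        body = _without_sites(_random_dna(5, 50), ["EcoRI"])
        # place GAATTC across the seam: TTC....GAA
        plasmid = NucSeq("p", "TTC" + body + "GAA", "circular")
        frags = digest(plasmid, ["EcoRI"])
        assert len(frags) == 1 and len(frags[0].body) == len(plasmid)

    def test_nucleotide_conservation_on_random_circular_substrates(self):
        names = ["EcoRI", "BamHI", "SbfI", "StuI"]
        for seed in range(25):
            rng = random.Random(1000 + seed)
            core = _without_sites(_random_dna(seed, 300), names)
            pieces = [core[i * 60 : (i + 1) * 60] for i in range(5)]
            sites = [ENZYMES[rng.choice(names)].site for _ in range(5)]
            seq = NucSeq("p", "".join(p + s for p, s in zip(pieces, sites)), "circular")
            frags = digest(seq, names)
            assert sum(len(f.body) for f in frags) == len(seq)


class TestLigate:
    def test_digest_ligate_round_trip_circular(self):
        body = _without_sites(_random_dna(6, 200), ["EcoRI", "BamHI"])
        seq = NucSeq("p", body[:90] + "GAATTC" + body[90:180] + "GGATCC", "circular")
        frags = digest(seq, ["EcoRI", "BamHI"])
        out = ligate(frags, circularize=True).construct.seq
        assert circularly_equal(out, seq)

    def test_digest_ligate_round_trip_linear(self):
        body = _without_sites(_random_dna(7, 150), ["XhoI"])
        seq = NucSeq("s", body[:70] + "CTCGAG" + body[70:])
        frags = digest(seq, ["XhoI"])
        out = ligate(frags, circularize=False).construct.seq
        assert out.bases == seq.bases

    def test_ecorI_religation_regenerates_site(self):
        body = _without_sites(_random_dna(8, 100), ["EcoRI"])
        seq = NucSeq("p", body + "GAATTC", "circular")
        result = ligate(digest(seq, ["EcoRI"]), circularize=True, enzymes=["EcoRI"])
        assert result.junctions[0].recut_by == ("EcoRI",)

    def test_bamhI_bglII_scar_is_never_recut(self):
        # excise a BamHI..BglII segment and re-ligate: scar GGATCT kills both sites
        filler = _without_sites(_random_dna(9, 120), ["BamHI", "BglII"])
        seq = NucSeq("p", filler[:40] + "GGATCC" + filler[40:80] + "AGATCT" + filler[80:],
                     "circular")
        frags = digest(seq, ["BamHI", "BglII"])
        assert len(frags) == 2
        backbone = max(frags, key=lambda f: len(f.body))
        result = ligate([backbone], circularize=True, enzymes=["BamHI", "BglII"])
        j = result.junctions[0]
        assert "GGATCT" in j.scar
        assert j.recut_by == ()

    def test_incompatible_overhangs_fail_naming_junction(self):
        a = SeqFragment("ACGTACGT", End("AATT", "5p"), End("AATT", "5p"), id="A")
        b = SeqFragment("TTGGCCAA", End("GATC", "5p"), End("GATC", "5p"), id="B")
        with pytest.raises(LigationError, match="junction 1"):
            ligate([a, b], circularize=False)

    def test_polarity_mismatch_fails(self):
        assert not ends_compatible(End("TGCA", "3p"), End("TGCA", "5p"))
        assert not ends_compatible(End("AATT", "5p"), End("", "blunt"))

    def test_blunt_joins_blunt(self):
        a = SeqFragment("AAAA", id="A")
        b = SeqFragment("TTTT", id="B")
        assert ligate([a, b], circularize=False).construct.seq.bases == "AAAATTTT"


class TestPcr:
    FWD = Primer("yBE0.6_F", "TTCCGggcgcgccCTGTGGGTGCAATGATTTAGAATG", 15)
    REV = Primer("yBE0.6_R", "TTGCCcctgcaggGTTATTGGCAGGTGATTTTGAGC", 15)

    def _template(self, seed=10, core_len=400):
        core = _random_dna(seed, core_len)
        return NucSeq("tpl", _random_dna(seed + 1, 40)
                      + "CTGTGGGTGCAATGATTTAGAATG" + core
                      + revcomp("GTTATTGGCAGGTGATTTTGAGC") + _random_dna(seed + 2, 40))

    def test_tailed_primers_appear_at_product_termini(self):
        product = simulate_pcr(self._template(), self.FWD, self.REV)
        assert product.body.startswith(self.FWD.full.upper())
        assert product.body.endswith(revcomp(self.REV.full.upper()))
        assert "GGCGCGCC" in product.body[:14]       # AscI tail
        assert "CCTGCAGG" in product.body[-14:]      # SbfI tail (on revcomp side)
        assert product.left_end.polarity == "blunt"

    def test_degenerate_primer_anneals_iupac_aware(self):
        # S at an annealing position matches template C
        tpl = NucSeq("t", _random_dna(11, 30) + "GAATTCCAAGGTTCC"
                     + _random_dna(12, 60) + "CCATTGGAACCTTGG" + _random_dna(13, 30))
        fwd = Primer("f", "GAATTCCAAGGTTCS", 15)   # S over terminal C
        rev = Primer("r", revcomp("CCATTGGAACCTTGG"), 15)
        product = simulate_pcr(tpl, fwd, rev)
        # annealed degenerate position resolves to the template base
        assert product.body.startswith("GAATTCCAAGGTTCC")

    def test_missing_reverse_footprint_fails(self):
        tpl = NucSeq("t", _random_dna(14, 60) + "CTGTGGGTGCAATGATTTAGAATG"
                     + _random_dna(15, 60))
        with pytest.raises(AmplificationError, match="no amplicon"):
            simulate_pcr(tpl, self.FWD, self.REV)

    def test_multiple_forward_sites_abort(self):
        site = "CTGTGGGTGCAATGATTTAGAATG"
        tpl = NucSeq("t", site + _random_dna(16, 50) + site
                     + revcomp("GTTATTGGCAGGTGATTTTGAGC"))
        with pytest.raises(AmplificationError, match="ambiguous"):
            simulate_pcr(tpl, self.FWD, self.REV)

    def test_wrong_orientation_fails(self):
        tpl = NucSeq("t", revcomp("GTTATTGGCAGGTGATTTTGAGC") + _random_dna(17, 30)
                     + "CTGTGGGTGCAATGATTTAGAATG")
        with pytest.raises(AmplificationError):
            simulate_pcr(tpl, self.FWD, self.REV)


class TestInfusion:
    def test_assembly_length_arithmetic(self):
        arm5, arm3 = _random_dna(18, 15), _random_dna(19, 15)
        vec = SeqFragment(arm3 + _random_dna(20, 300) + arm5, id="vec")
        ins = SeqFragment(arm5 + _random_dna(21, 120) + arm3, id="ins")
        cm = infusion_assemble(vec, ins, arm_len=15)
        assert cm.seq.topology == "circular"
        assert len(cm.seq) == len(vec.body) + len(ins.body) - 30

    def test_single_mismatched_arm_fails(self):
        arm5, arm3 = _random_dna(22, 15), _random_dna(23, 15)
        vec = SeqFragment(arm3 + _random_dna(24, 100) + arm5, id="vec")
        bad = SeqFragment(arm5 + _random_dna(25, 50) + "A" * 15, id="ins")
        with pytest.raises(AssemblyError, match="3' homology arm"):
            infusion_assemble(vec, bad, arm_len=15)

    def test_assemble_digest_religate_round_trip(self):
        arm5, arm3 = "AAATTTGGGCCCAAA", "CCCGGGTTTAAACCC"
        mid_v = _without_sites(_random_dna(26, 200), ["EcoRI"])
        mid_i = _without_sites(_random_dna(27, 90), ["EcoRI"])
        vec = SeqFragment(arm3 + mid_v + "GAATTC" + mid_v[:40] + arm5, id="vec")
        ins = SeqFragment(arm5 + mid_i + arm3, id="ins")
        cm = infusion_assemble(vec, ins)
        frags = digest(cm, ["EcoRI"])
        assert len(frags) == 1
        out = ligate(frags, circularize=True).construct.seq
        assert circularly_equal(out, cm.seq)
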