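"""Spacer recipes, vector assembly, verification, and part surgery."""

import random
from io import StringIO

import pytest

from rlgl.clonesim import digest
from rlgl.designer import (
    DesignConfig,
    DesignError,
    Part,
    assemble_reporter_vector,
    design_spacer,
    load_config,
    remove_feature_by_digestion,
    replace_feature_by_digestion,
    verify_design,
)
from rlgl.enzymes import ENZYMES
from rlgl.fixtures import demo_reporter_config, random_dna
from rlgl.motifscrub import hox_spacer_rules, scrub_noncoding, verify_clean
from rlgl.seqcore import NucSeq, circularly_equal, genbank_to_string, read_genbank

SPACER_RULES = hox_spacer_rules(site_names=("NheI", "SbfI", "SpeI", "SacII", "AgeI"))


def _donor(seed, n=8000):
    return NucSeq("donor", random_dna(random.Random(seed), n))


class TestDesignSpacer:
    def test_zero_target_is_empty_and_clean(self):
        spacer, rep = design_spacer(_donor(0, 100), 0, SPACER_RULES, seed=1)
        assert len(spacer) == 0 and rep.converged
        assert verify_clean(spacer, SPACER_RULES)[0]

    def test_tandem_recipe_doubles_and_cleans(self):
        spacer, rep = design_spacer(_donor(1, 1000), 2, SPACER_RULES, seed=5)
        assert len(spacer) == 2000
        assert rep.converged
        assert verify_clean(spacer, SPACER_RULES)[0]

    def test_scramble_recipe_length_and_cleanliness(self):
        spacer, rep = design_spacer(_donor(2, 4000), 4, SPACER_RULES, seed=9)
        assert len(spacer) == 4000
        assert verify_clean(spacer, SPACER_RULES)[0]

    def test_deterministic_in_source_and_seed(self):
        a, _ = design_spacer(_donor(3, 4000), 4, SPACER_RULES, seed=11)
        b, _ = design_spacer(_donor(3, 4000), 4, SPACER_RULES, seed=11)
        c, _ = design_spacer(_donor(3, 4000), 4, SPACER_RULES, seed=12)
        assert a.bases == b.bases
        assert a.bases != c.bases  # scramble stage is seed-driven

    def test_bad_target_rejects(self):
        with pytest.raises(DesignError):
            design_spacer(_donor(4, 100), 3, SPACER_RULES, seed=1)

    def test_short_donor_rejects(self):
        with pytest.raises(DesignError):
            design_spacer(_donor(5, 500), 2, SPACER_RULES, seed=1)


class TestAssemblyArithmetic:
    def test_parts_plus_junction_sites(self):
        rng = random.Random(6)
        lengths = (300, 700, 250, 2000, 690, 250, 720, 300)
        parts = [Part(f"p{i}", "misc", NucSeq(f"p{i}", random_dna(rng, n)))
                 for i, n in enumerate(lengths)]
        eight_bp = ["AscI", "FseI", "NotI", "SbfI", "AscI", "FseI", "NotI"]
        cfg = DesignConfig("v", parts, [[e] for e in eight_bp], unique_cutters=[])
        report = assemble_reporter_vector(cfg)
        assert len(report.assembled.seq) == sum(lengths) + 7 * 8
        assert report.assembled.seq.topology == "circular"

    def test_duplicate_part_labels_reject(self):
        p = Part("x", "misc", NucSeq("x", "ACGT"))
        with pytest.raises(DesignError):
            DesignConfig("v", [p, p], [[]], [])

    def test_junction_count_mismatch_rejects(self):
        p = Part("x", "misc", NucSeq("x", "ACGT"))
        q = Part("y", "misc", NucSeq("y", "ACGT"))
        with pytest.raises(DesignError):
            DesignConfig("v", [p, q], [], [])


class TestDemoDesign:
    def test_all_checks_pass(self):
        report = assemble_reporter_vector(demo_reporter_config(seed=42))
        assert report.passed, [c for c in report.checks if not c.passed]
        names = {c.name for c in report.checks}
        assert "unique_cutter_AscI" in names
        assert "clean_spacer" in names
        assert "cds_translates_proximal_reporter" in names
        assert "promoter_upstream_of_distal_reporter" in names

    def test_genbank_round_trip_is_a_fixed_point(self):
        cfg = demo_reporter_config(seed=8)
        report = assemble_reporter_vector(cfg)
        back = read_genbank(StringIO(genbank_to_string(report.assembled)))
        assert back.seq.bases == report.assembled.seq.bases
        re_checks = verify_design(back, cfg)
        assert [(c.name, c.passed) for c in re_checks] == \
               [(c.name, c.passed) for c in report.checks]

    def test_planted_second_site_fails_unique_cutter_check(self):
        cfg = demo_reporter_config(seed=9)
        spacer = cfg.part("spacer")
        sab = spacer.seq.bases
        sab = sab[:500] + ENZYMES["AscI"].site + sab[500 + 8:]
        bad = cfg.with_part("spacer", Part("spacer", "spacer", spacer.seq.with_bases(sab), "+"))
        report = assemble_reporter_vector(bad)
        fail = [c for c in report.checks if c.name == "unique_cutter_AscI"][0]
        assert not fail.passed
        assert fail.evidence.count(",") >= 1  # both positions listed

    def test_premature_stop_fails_translation_check(self):
        cfg = demo_reporter_config(seed=10)
        cds = cfg.part("proximal_reporter")
        broken = cds.seq.bases[:30] + "TAA" + cds.seq.bases[33:]
        bad = cfg.with_part("proximal_reporter",
                            Part("proximal_reporter", "CDS", cds.seq.with_bases(broken), "+"))
        report = assemble_reporter_vector(bad)
        fail = [c for c in report.checks if c.name == "cds_translates_proximal_reporter"][0]
        assert not fail.passed and "codon 11" in fail.evidence

    def test_missing_promoter_fails_layout_check(self):
        cfg = demo_reporter_config(seed=11)
        prom = cfg.part("proximal_promoter")
        # demote the promoter to a generic part: the CDS loses its 5' promoter
        bad = cfg.with_part("proximal_promoter",
                            Part("proximal_promoter", "misc", prom.seq, "+"))
        report = assemble_reporter_vector(bad)
        fail = [c for c in report.checks
                if c.name == "promoter_upstream_of_proximal_reporter"][0]
        assert not fail.passed


class TestPartSurgery:
    def test_spacer_excision_mirrors_religation(self):
        cfg = demo_reporter_config(seed=12)
        report = assemble_reporter_vector(cfg)
        cm = report.assembled
        spacer_len = len(cfg.part("spacer").seq)
        result = remove_feature_by_digestion(cm, "spacer", ("BamHI", "BglII"))
        out = result.construct.seq
        # removed: spacer + both 6 bp sites, replaced by the 6 bp scar
        assert len(out) == len(cm.seq) - spacer_len - 6
        j = result.junctions[0]
        assert "GGATCT" in j.scar
        assert j.recut_by == ()

    def test_enhancer_swap_two_route_equivalence(self):
        cfg = demo_reporter_config(seed=13)
        cm = assemble_reporter_vector(cfg).assembled

        rng = random.Random(99)
        enh2, _ = scrub_noncoding(NucSeq("enhancer", random_dna(rng, 500)),
                                  cfg.forbidden_rules)
        # route A: cut out the old enhancer, ligate in an AscI/SbfI-flanked insert
        donor = NucSeq("donor", "TTTT" + ENZYMES["AscI"].site + enh2.bases
                       + ENZYMES["SbfI"].site + "TTTT")
        middle = digest(donor, ["AscI", "SbfI"])[1]
        swapped = replace_feature_by_digestion(cm, "enhancer", middle, ("AscI", "SbfI"))

        # route B: re-assemble from the edited config
        cfg2 = cfg.with_part("enhancer", Part("enhancer", "enhancer", enh2, "+"))
        rebuilt = assemble_reporter_vector(cfg2).assembled
        assert circularly_equal(swapped.construct.seq, rebuilt.seq)


class TestYamlConfig:
    def test_load_and_assemble(self, tmp_path):
        cfgfile = tmp_path / "design.yaml"
        cfgfile.write_text(
            "vector_id: mini\n"
            "parts:\n"
            "  - {label: left, kind: misc, seq: ACGTACGTAC}\n"
            "  - {label: right, kind: misc, seq: TTGGCCAATT, orientation: '-'}\n"
            "junctions: [[EcoRI]]\n"
            "unique_cutters: [EcoRI]\n"
            "forbidden:\n"
            "  - {pattern: TTTAT, label: AbdB, action: fixed, replacement: TTGGG}\n"
            "  - {site: NheI}\n"
        )
        cfg = load_config(cfgfile)
        assert [r.label for r in cfg.forbidden_rules] == ["AbdB", "NheI"]
        report = assemble_reporter_vector(cfg)
        assert len(report.assembled.seq) == 10 + 6 + 10
        assert report.passed

    def test_missing_key_rejects(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("vector_id: x\nparts: []\n")
        with pytest.raises(DesignError, match="junctions"):
            load_config(f)
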