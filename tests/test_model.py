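"""Glycan tree model: composition tallies, serialization, grammar
validation and motif matching."""

import pytest

from glycanpipe import (
    Composition,
    GlycanStructure,
    GrammarError,
    Node,
    StructureError,
    composition_of,
    match_motifs,
    parse_structure,
    validate_structure,
)
from glycanpipe.model import mannose_scaffolds


class TestComposition:
    def test_string_round_trip(self):
        c = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        assert (c.hex, c.hexnac, c.fuc) == (5, 2, 1)
        assert str(c) == "Hex5HexNAc2Fuc1"

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            Composition.from_string("Hex5Xyl1")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Composition(hex=-1)


class TestCompositionOf:
    def test_core_fucosylated_paucimannose(self):
        s = parse_structure(
            "PA:GlcNAc(Fuc@a6,GlcNAc@b4(Man@b4(Man@a3,Man@a6)))"
        )
        assert str(composition_of(s)) == "Hex3HexNAc2Fuc1"
        assert composition_of(s).label_state == "PA"

    def test_galfuc_isoform_tally(self, galfuc_structure):
        # GalFuc on the proximal GlcNAc with a Man4 backbone
        assert str(composition_of(galfuc_structure)) == "Hex5HexNAc2Fuc1"

    def test_single_residue(self):
        s = GlycanStructure(Node("HexNAc", "GlcNAc"), "PA")
        c = composition_of(s)
        assert str(c) == "HexNAc1" and c.label_state == "PA"

    def test_cycle_detected(self):
        a = Node("HexNAc", "GlcNAc")
        b = Node("Hex", "Man", (), "b", 4)
        a.children.append(b)
        b.children.append(a)
        with pytest.raises(StructureError):
            composition_of(GlycanStructure(a, "free"))

    def test_conserved_under_leaf_removal(self, sampled_panel):
        # removing any leaf decrements exactly its own residue/substituents
        for orig, _ in sampled_panel[:40]:
            s = orig.copy()
            parent_of = {}
            for n in s.nodes():
                for c in n.children:
                    parent_of[id(c)] = n
            leaves = [n for n in s.nodes() if not n.children and id(n) in parent_of]
            total = composition_of(s).counts()
            for leaf in leaves:
                parent_of[id(leaf)].children.remove(leaf)
                reduced = composition_of(s).counts()
                parent_of[id(leaf)].children.append(leaf)
                diff = {k: total[k] - reduced[k] for k in total}
                assert diff[leaf.residue] == 1
                for sub in leaf.substituents:
                    assert diff[sub] == 1
                assert sum(diff.values()) == 1 + len(leaf.substituents)


class TestSerialization:
    def test_round_trip_exact(self, sampled_panel):
        for s, _ in sampled_panel:
            text = s.serialize()
            back = parse_structure(text)
            assert back.serialize() == text
            assert back == s

    def test_mass_canonical_strips_identity(self, lacdinac_structure):
        assert "GalNAc" not in lacdinac_structure.mass_canonical()
        assert "GalNAc" in lacdinac_structure.canonical()

    def test_root_label_required(self):
        with pytest.raises(ValueError):
            parse_structure("GlcNAc")


class TestGrammarValidation:
    def test_sampled_structures_validate(self, sampled_panel, n_grammar):
        for s, _ in sampled_panel:
            validate_structure(s, n_grammar)

    def test_rejects_tetra_antennary(self, n_grammar):
        s = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4("
            "Man@a3(GlcNAc@b2,GlcNAc@b4),"
            "Man@a6(GlcNAc@b2,GlcNAc@b4))))"
        )
        with pytest.raises(GrammarError):
            validate_structure(s, n_grammar)

    def test_rejects_hexa_in_n_glycans(self, n_grammar):
        s = parse_structure("PA:GlcNAc(GlcNAc@b4(Man@b4(GlcA@b4)))")
        with pytest.raises(GrammarError):
            validate_structure(s, n_grammar)

    def test_rejects_pc_on_hexose(self, n_grammar):
        s = parse_structure("PA:GlcNAc(GlcNAc@b4(Man+PC@b4(Man@a3,Man@a6)))")
        with pytest.raises(GrammarError):
            validate_structure(s, n_grammar)

    def test_rejects_noncanonical_mannose(self, n_grammar):
        # alpha-1,2-mannose without the complete Man5 base
        s = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(Man@a2),Man@a6)))"
        )
        with pytest.raises(GrammarError):
            validate_structure(s, n_grammar)

    def test_requires_chitobiose_core(self, n_grammar):
        s = parse_structure("PA:GlcNAc(Fuc@a6)")
        with pytest.raises(GrammarError):
            validate_structure(s, n_grammar)

    def test_scaffold_count(self):
        assert len(mannose_scaffolds()) == 21
        # the Man5 and Man9 scaffolds are unique
        assert sum(1 for s in mannose_scaffolds() if len(s) == 5) == 1
        assert sum(1 for s in mannose_scaffolds() if len(s) == 9) == 1


class TestMatchMotifs:
    def test_galfuc_core(self, galfuc_structure, n_grammar):
        names = {name for name, _ in match_motifs(galfuc_structure, n_grammar)}
        assert "GalFuc-core" in names
        assert "core-a6-fucose" in names

    def test_lacdinac(self, lacdinac_structure, n_grammar):
        names = {name for name, _ in match_motifs(lacdinac_structure, n_grammar)}
        assert "LacdiNAc" in names

    def test_bare_core_has_no_motifs(self, n_grammar):
        s = parse_structure("PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3,Man@a6)))")
        assert match_motifs(s, n_grammar) == []

    def test_deterministic_preorder(self, sampled_panel, n_grammar):
        for s, _ in sampled_panel[:20]:
            a = match_motifs(s, n_grammar)
            b = match_motifs(s.copy(), n_grammar)
            assert a == b
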