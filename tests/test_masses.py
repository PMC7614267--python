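"""Mass engine: neutral masses, integer labels, fragment enumeration and
B/Y complementarity."""

import pytest

from glycanpipe import (
    Composition,
    NEGATIVE,
    POSITIVE,
    complementarity_check,
    composition_of,
    enumerate_fragments,
    mz_label,
    neutral_mass,
    parse_structure,
    precursor_mz,
)
from glycanpipe.masses import TRIMETHYLAMINE, WATER, fragment_table

from reference_ions import PRECURSOR_LABELS


class TestNeutralMass:
    def test_difucosylated_paucimannose(self):
        c = Composition.from_string("Hex3HexNAc2Fuc2", "PA")
        assert neutral_mass(c) == pytest.approx(1280.51, abs=0.01)
        assert precursor_mz(c, POSITIVE) == pytest.approx(1281.51, abs=0.01)

    def test_empty_composition_is_water(self):
        assert neutral_mass(Composition()) == pytest.approx(18.0106, abs=1e-6)

    def test_reduced_pc_o_glycan(self):
        # GalNAc-ol chain with hexuronic acid and phosphorylcholine
        c = Composition.from_string("HexNAc2HexA1PC1", "alditol")
        assert neutral_mass(c) == pytest.approx(767.27, abs=0.01)
        assert precursor_mz(c, NEGATIVE) == pytest.approx(766.27, abs=0.01)

    def test_additivity(self, sampled_panel):
        # mass(parent) - mass(after removing a subtree) equals the removed
        # residue/substituent sum exactly
        from glycanpipe.masses import RESIDUE_MASS, SUBSTITUENT_MASS

        for orig, _ in sampled_panel[:30]:
            s = orig.copy()
            parent_mass = neutral_mass(composition_of(s))
            for node in s.nodes():
                for child in list(node.children):
                    node.children.remove(child)
                    reduced = neutral_mass(composition_of(s))
                    node.children.append(child)
                    removed = composition_of(
                        type(s)(child.copy(), "free")
                    ).counts()
                    expect = sum(
                        RESIDUE_MASS[k] * v
                        for k, v in removed.items()
                        if k in RESIDUE_MASS
                    ) + sum(
                        SUBSTITUENT_MASS[k] * v
                        for k, v in removed.items()
                        if k in SUBSTITUENT_MASS
                    )
                    assert parent_mass - reduced == pytest.approx(expect, abs=1e-9)


class TestMzLabel:
    def test_truncation_not_rounding(self):
        assert mz_label(1637.60) == 1637
        assert mz_label(2235.85) == 2235
        assert mz_label(100.00) == 100

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mz_label(0.0)

    @pytest.mark.parametrize("comp_s,label_state,sign,label", PRECURSOR_LABELS)
    def test_printed_precursor_labels(self, comp_s, label_state, sign, label):
        c = Composition.from_string(comp_s, label_state)
        mode = POSITIVE if sign > 0 else NEGATIVE
        assert mz_label(precursor_mz(c, mode)) == label


class TestEnumerateFragments:
    def test_galfuc_y1_at_608(self, galfuc_structure):
        labels = {f.label for f in enumerate_fragments(galfuc_structure, POSITIVE, 2)}
        assert 608 in labels

    def test_y1_shifts_to_446_after_galactose_removal(self, galfuc_structure):
        # in-silico removal of the galactose on the core fucose
        s = galfuc_structure.copy()
        fuc = next(c for c in s.root.children if c.residue == "Fuc")
        fuc.children.clear()
        labels = {f.label for f in enumerate_fragments(s, POSITIVE, 2)}
        assert 446 in labels and 608 not in labels

    def test_single_residue_has_no_cut_fragments(self):
        s = parse_structure("PA:GlcNAc")
        assert enumerate_fragments(s, POSITIVE, 1) == []

    def test_pc_o_glycan_trimethylamine_loss(self):
        s = parse_structure("ol:GalNAc(GlcA@b6(GlcNAc+PC@b4))")
        prec = precursor_mz(composition_of(s), NEGATIVE)
        frags = enumerate_fragments(s, NEGATIVE, 2)
        assert any(
            f.kind == "precursor"
            and "trimethylamine" in f.losses
            and f.mz == pytest.approx(prec - TRIMETHYLAMINE, abs=1e-6)
            for f in frags
        )

    def test_z_ions_in_negative_mode(self):
        s = parse_structure("ol:GalNAc(Gal@b3)")
        frags = enumerate_fragments(s, NEGATIVE, 1)
        ys = [f for f in frags if f.kind == "Y"]
        zs = [f for f in frags if f.kind == "Z"]
        assert ys and zs
        assert zs[0].mz == pytest.approx(ys[0].mz - WATER, abs=1e-6)

    def test_co2_loss_only_for_subterminal_hexa(self):
        sub = parse_structure("ol:GalNAc(GlcA@b6(GlcNAc+PC@b4))")
        term = parse_structure("ol:GalNAc(GlcNAc+PC@b6(GlcA@b4))")
        has_co2 = lambda s: any(
            "CO2" in f.losses for f in enumerate_fragments(s, NEGATIVE, 2)
        )
        assert has_co2(sub)
        assert not has_co2(term)

    def test_rejects_bad_max_cuts(self, galfuc_structure):
        with pytest.raises(ValueError):
            enumerate_fragments(galfuc_structure, POSITIVE, 3)

    def test_table_export(self, galfuc_structure):
        df = fragment_table(enumerate_fragments(galfuc_structure, POSITIVE, 1))
        assert set(df.columns) >= {"type", "label", "mz", "composition"}
        assert len(df) > 0


class TestComplementarity:
    def test_single_cut_pairs_reconstruct_precursor(self, galfuc_structure):
        prec = precursor_mz(composition_of(galfuc_structure), POSITIVE)
        frags = enumerate_fragments(galfuc_structure, POSITIVE, 1)
        bs = {f.cut_edges: f for f in frags if f.kind == "B"}
        ys = {f.cut_edges: f for f in frags if f.kind == "Y"}
        assert bs and set(bs) == set(ys)
        for edge, b in bs.items():
            assert complementarity_check(b, ys[edge], prec)

    def test_mismatched_edges_fail(self, galfuc_structure):
        prec = precursor_mz(composition_of(galfuc_structure), POSITIVE)
        frags = enumerate_fragments(galfuc_structure, POSITIVE, 1)
        bs = [f for f in frags if f.kind == "B"]
        ys = [f for f in frags if f.kind == "Y"]
        pair = next(
            (b, y) for b in bs for y in ys if b.cut_edges != y.cut_edges
        )
        assert not complementarity_check(pair[0], pair[1], prec)

    def test_requires_b_and_y(self, galfuc_structure):
        frags = enumerate_fragments(galfuc_structure, POSITIVE, 1)
        b = next(f for f in frags if f.kind == "B")
        with pytest.raises(ValueError):
            complementarity_check(b, b, 1000.0)
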