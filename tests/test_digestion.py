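"""Reagent specificities, digestion-product prediction and shift
interpretation."""

import random

import pytest

from glycanpipe import (
    DigestionObservation,
    enumerate_candidates,
    interpret_shift,
    parse_structure,
    predict_products,
)
from glycanpipe.digestion import (
    default_panel,
    predict_product_labels,
    structure_label,
)
from glycanpipe.model import Composition
from glycanpipe.synthetic import simulate_digestion


@pytest.fixture(scope="module")
def panel():
    return default_panel()


class TestPredictProducts:
    def test_hex4_releases_lacdinac_galnac(self, lacdinac_structure, panel):
        assert structure_label(lacdinac_structure) == 1541
        labels = predict_product_labels(lacdinac_structure, panel["hex4"])
        assert 1338 in labels

    def test_beta_galactosidase_trims_core_galfuc(self, galfuc_structure, panel):
        assert structure_label(galfuc_structure) == 1459
        for reagent in ("nidulans-bgal", "niger-bgal"):
            assert predict_product_labels(galfuc_structure, panel[reagent]) == {1297}

    def test_alpha16_core_fucose_resists_hf(self, panel):
        s = parse_structure(
            "PA:GlcNAc(Fuc@a6,GlcNAc@b4(Man@b4(Man@a3,Man@a6)))"
        )
        assert predict_product_labels(s, panel["hf"]) == {structure_label(s)}

    def test_hf_removes_a3_fucose_with_its_galactose(self, panel):
        s = parse_structure(
            "PA:GlcNAc(Fuc@a3(Gal@a?),GlcNAc@b4(Man@b4(Man@a3,Man@a6)))"
        )
        parent = structure_label(s)
        # fucose leaves together with the attached galactose: -308
        assert predict_product_labels(s, panel["hf"]) == {parent - 308}

    def test_niger_bisect_blocked_by_distal_fucose(self, panel):
        free = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Gal@b4,Man@a3,Man@a6)))"
        )
        blocked = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Fuc@a3,Man@b4(Gal@b4,Man@a3,Man@a6)))"
        )
        assert predict_product_labels(free, panel["niger-bgal"]) == {
            structure_label(free) - 162
        }
        assert predict_product_labels(blocked, panel["niger-bgal"]) == {
            structure_label(blocked)
        }
        # A. nidulans never reaches the bisect
        assert predict_product_labels(free, panel["nidulans-bgal"]) == {
            structure_label(free)
        }

    def test_coffee_agal_reaches_fucose_and_mannose_galactose(self, panel):
        s = parse_structure(
            "PA:GlcNAc(Fuc@a3(Gal@a?),GlcNAc@b4(Man@b4(Man@a3(Gal@a?),Man@a6)))"
        )
        assert predict_product_labels(s, panel["coffee-agal"]) == {
            structure_label(s) - 324
        }

    def test_fucm_spares_methylated_bisect_fucose(self, panel):
        plain = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Gal@b4(Fuc@a2),Man@a3,Man@a6)))"
        )
        methylated = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Gal@b4(Fuc+Me@a2),Man@a3,Man@a6)))"
        )
        assert predict_product_labels(plain, panel["fucm"]) == {
            structure_label(plain) - 146
        }
        assert predict_product_labels(methylated, panel["fucm"]) == {
            structure_label(methylated)
        }

    def test_jackbean_hex_spares_pc_chains(self, panel):
        protected = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(GlcNAc+PC@b2(GlcNAc@b4)),Man@a6)))"
        )
        # terminal HexNAc sits in a PC-modified chain: resistant
        assert predict_product_labels(protected, panel["jackbean-hex"]) == {
            structure_label(protected)
        }
        plain = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(GlcNAc@b2(GlcNAc@b4)),Man@a6)))"
        )
        assert predict_product_labels(plain, panel["jackbean-hex"]) == {
            structure_label(plain) - 406
        }

    def test_pce_partiality_yields_all_intermediates(self, panel):
        s = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(GlcNAc+PC@b2,GlcNAc+PC@b4),Man@a6)))"
        )
        parent = structure_label(s)
        assert predict_product_labels(s, panel["pce"]) == {
            parent, parent - 165, parent - 330
        }

    def test_unknown_terminal_identity_branches_hex4(self, panel):
        # unknown epimer identity: removal is admissible, not mandatory
        s = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(GlcNAc@b2(HexNAc@b4)),Man@a6)))"
        )
        parent = structure_label(s)
        assert predict_product_labels(s, panel["hex4"]) == {parent, parent - 203}

    def test_mass_bookkeeping(self, sampled_panel, panel):
        # parent label minus product label equals the floor-consistent sum
        # of removed residues for every prediction
        from glycanpipe.masses import POSITIVE, precursor_mz, mz_label
        from glycanpipe.model import composition_of

        for s, _ in sampled_panel[:25]:
            parent_label = structure_label(s)
            for reagent in panel.values():
                for product, label in predict_products(s, reagent):
                    assert label == mz_label(
                        precursor_mz(composition_of(product), POSITIVE)
                    )
                    assert label <= parent_label

    def test_confluence_of_complete_reagents(self, sampled_panel, panel):
        # a joint digest (each complete reagent applied repeatedly until no
        # further change) reaches the same terminal product regardless of
        # the order of application, even when one enzyme exposes substrate
        # for the other
        def joint_fixpoint(s, order):
            cur = s
            while True:
                changed = False
                for name in order:
                    products = predict_products(cur, panel[name])
                    assert len(products) == 1  # complete, no admissible branch
                    nxt, label = products[0]
                    if label != structure_label(cur):
                        changed = True
                    cur = nxt
                if not changed:
                    return structure_label(cur)

        pairs = [("niger-bgal", "coffee-agal"), ("a23-man", "jackbean-hex")]
        for s, _ in sampled_panel[:10]:
            for r1, r2 in pairs:
                assert joint_fixpoint(s, (r1, r2)) == joint_fixpoint(s, (r2, r1))


class TestInterpretShift:
    def test_beta_gal_shift_selects_core_galfuc_isomer(self, n_grammar):
        comp = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        candidates = enumerate_candidates(comp, n_grammar).structures
        obs = DigestionObservation(1459, "nidulans-bgal", 1297)
        shift = interpret_shift(obs, candidates, grammar=n_grammar)
        assert shift.survivors and not shift.conflict
        assert all(
            any(
                c.residue == "Fuc" and c.children
                for c in s.root.children
            )
            for s in shift.survivors
        )
        assert "GalFuc-core" in shift.assertions

    def test_unchanged_product_keeps_resistant_candidates(self, n_grammar):
        comp = Composition.from_string("Hex7HexNAc2", "PA")
        candidates = enumerate_candidates(comp, n_grammar).structures
        obs = DigestionObservation(1637, "hf", 1637)
        shift = interpret_shift(obs, candidates, grammar=n_grammar)
        assert len(shift.survivors) == len(candidates)

    def test_impossible_product_flags_conflict(self, n_grammar):
        comp = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        candidates = enumerate_candidates(comp, n_grammar).structures
        obs = DigestionObservation(1459, "nidulans-bgal", 1100)
        shift = interpret_shift(obs, candidates, grammar=n_grammar)
        assert shift.conflict and shift.survivors == []

    def test_unknown_reagent_rejected(self, galfuc_structure):
        obs = DigestionObservation(1459, "nidulans-bgal", 1297)
        with pytest.raises(KeyError):
            interpret_shift(
                DigestionObservation(1459, "nope", 1297), [galfuc_structure]
            )

    def test_product_cannot_exceed_parent(self):
        with pytest.raises(ValueError):
            DigestionObservation(1459, "hf", 1500)


class TestSimulateDigestion:
    def test_observations_are_admissible(self, sampled_panel, panel, noise_free_cfg):
        rng = random.Random(8)
        for s, _ in sampled_panel[:30]:
            for obs in simulate_digestion(s, cfg=noise_free_cfg, rng=rng):
                assert obs.product_label in predict_product_labels(
                    s, panel[obs.reagent]
                )
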