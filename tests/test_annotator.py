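"""Candidate enumeration and evidence-ranked annotation."""

import random

import pytest

from glycanpipe import (
    Composition,
    DigestionObservation,
    GlycanStructure,
    GrammarError,
    Node,
    StructureError,
    annotate,
    composition_of,
    enumerate_candidates,
    parse_structure,
    validate_structure,
)
from glycanpipe.annotate import AnnotatorConfig, _proximal_state
from glycanpipe.digestion import RECOVERY_PANEL
from glycanpipe.io import write_report
from glycanpipe.synthetic import simulate_digestion, simulate_spectrum

# ---------------------------------------------------------------------------
# independent enumeration oracle: residue-by-residue attachment + validation
# ---------------------------------------------------------------------------

_VOCAB = [
    ("HexNAc", "GlcNAc", (), "b", 4),
    ("HexNAc", "GlcNAc", (), "b", 2),
    ("HexNAc", "GlcNAc", ("PC",), "b", 4),
    ("HexNAc", "GlcNAc", ("PC",), "b", 2),
    ("Fuc", "Fuc", (), "a", 3),
    ("Fuc", "Fuc", (), "a", 6),
    ("Fuc", "Fuc", (), "a", 2),
    ("Fuc", "Fuc", ("Me",), "a", 2),
    ("Hex", "Man", (), "b", 4),
    ("Hex", "Man", (), "a", 2),
    ("Hex", "Man", (), "a", 3),
    ("Hex", "Man", (), "a", 6),
    ("Hex", "Gal", (), "b", 4),
    ("Hex", "Gal", (), "b", None),
    ("Hex", "Gal", (), "a", None),
]


def oracle_enumerate(target: Composition, grammar) -> set:
    """Grow trees one residue at a time through locally grammar-valid
    states; collect the mass-canonical forms of fully valid structures
    with the target composition."""

    def counts_leq(c):
        t, cc = target.counts(), c.counts()
        return all(cc[k] <= t[k] for k in t)

    start = GlycanStructure(Node("HexNAc", "GlcNAc"), target.label_state)
    seen = {start.canonical()}
    frontier = [start]
    hits = set()
    while frontier:
        st = frontier.pop()
        if composition_of(st).counts() == target.counts():
            try:
                validate_structure(st, grammar)
                hits.add(st.mass_canonical())
            except (GrammarError, StructureError):
                pass
            continue
        for idx in range(len(st.nodes())):
            for res, ident, subs, anomer, pos in _VOCAB:
                new = st.copy()
                new.nodes()[idx].children.append(Node(res, ident, subs, anomer, pos))
                if not counts_leq(composition_of(new)):
                    continue
                key = new.canonical()
                if key in seen:
                    continue
                try:
                    validate_structure(new, grammar, require_core=False)
                except (GrammarError, StructureError):
                    continue
                seen.add(key)
                frontier.append(new)
    return hits


class TestEnumerateCandidates:
    def test_difucosylated_isomer_count(self, n_grammar):
        comp = Composition.from_string("Hex3HexNAc2Fuc2", "PA")
        cands = enumerate_candidates(comp, n_grammar)
        assert len(cands.structures) >= 5

    def test_oligomannose_composition_has_unique_topology_per_series(self, n_grammar):
        # Hex9HexNAc2 admits only the canonical Man9 topology
        comp = Composition.from_string("Hex9HexNAc2", "PA")
        cands = enumerate_candidates(comp, n_grammar)
        assert len(cands.structures) == 1
        names = cands.structures[0].serialize()
        assert "Gal" not in names and "Fuc" not in names

    def test_hexa_composition_rejected_with_reason(self, n_grammar):
        comp = Composition.from_string("Hex3HexNAc2HexA1", "PA")
        cands = enumerate_candidates(comp, n_grammar)
        assert cands.structures == [] and "anionic" in cands.reason

    def test_truncation_flag(self, n_grammar):
        comp = Composition.from_string("Hex5HexNAc6PC2Fuc1", "PA")
        cands = enumerate_candidates(comp, n_grammar, cap=3)
        assert cands.truncated and len(cands.structures) == 3

    @pytest.mark.parametrize(
        "comp_s",
        ["Hex3HexNAc2Fuc1", "Hex2HexNAc2Fuc2", "Hex2HexNAc4PC1", "Hex4HexNAc2Fuc1"],
    )
    def test_agrees_with_attachment_oracle(self, comp_s, n_grammar):
        comp = Composition.from_string(comp_s, "PA")
        mine = {
            s.mass_canonical()
            for s in enumerate_candidates(comp, n_grammar).structures
        }
        assert mine == oracle_enumerate(comp, n_grammar)

    def test_sampled_truth_always_enumerated(self, sampled_panel, n_grammar):
        for s, _ in sampled_panel[:60]:
            cands = enumerate_candidates(composition_of(s), n_grammar)
            assert s.mass_canonical() in {
                x.mass_canonical() for x in cands.structures
            }

    def test_deduplicated_and_sorted(self, n_grammar):
        comp = Composition.from_string("Hex4HexNAc2Fuc2", "PA")
        structs = enumerate_candidates(comp, n_grammar).structures
        keys = [s.canonical() for s in structs]
        assert keys == sorted(keys) and len(keys) == len(set(keys))


def _annotate_truth(structure, cfg, rng, reagents=RECOVERY_PANEL):
    pl = simulate_spectrum(structure, cfg, rng)
    digs = simulate_digestion(structure, reagents=list(reagents), cfg=cfg, rng=rng)
    return annotate(pl, digs), pl, digs


class TestAnnotate:
    def test_core_galfuc_assignment(self, galfuc_structure, noise_free_cfg):
        # MS/MS with the m/z 608 Y1 plus the 1459 -> 1297 beta-gal shift
        rng = random.Random(2)
        pl = simulate_spectrum(galfuc_structure, noise_free_cfg, rng)
        digs = [DigestionObservation(1459, "nidulans-bgal", 1297)]
        res = annotate(pl, digs)
        assert str(res.composition) == "Hex5HexNAc2Fuc1"
        top = res.annotations[0]
        assert _proximal_state(top.structure) == (1, 1)

    def test_proximal_difucosylation_from_y1_and_hf(self, noise_free_cfg):
        s = parse_structure(
            "PA:GlcNAc(Fuc@a3,Fuc@a6,GlcNAc@b4(Man@b4(Man@a3,Man@a6)))"
        )
        rng = random.Random(3)
        res, _, _ = _annotate_truth(s, noise_free_cfg, rng, reagents=("hf",))
        assert _proximal_state(res.annotations[0].structure)[0] == 2

    def test_determinism(self, galfuc_structure, noise_free_cfg, tmp_path):
        outs = []
        for _ in range(2):
            rng = random.Random(7)
            res, _, _ = _annotate_truth(galfuc_structure, noise_free_cfg, rng)
            path = tmp_path / f"report-{_}.txt"
            write_report([res], path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_digestion_evidence_is_monotone(self, sampled_panel, noise_free_cfg):
        # adding a supporting digestion observation never lowers the rank
        # of the generating structure
        rng = random.Random(13)
        for s, _ in sampled_panel[:20]:
            pl = simulate_spectrum(s, noise_free_cfg, rng)
            digs = simulate_digestion(
                s, reagents=list(RECOVERY_PANEL), cfg=noise_free_cfg, rng=rng
            )
            key = s.mass_canonical()

            def truth_rank(res):
                for a in res.annotations:
                    if any(x.mass_canonical() == key for x in a.structures()):
                        return a.rank
                return len(res.annotations) + 1

            prev = truth_rank(annotate(pl, []))
            for k in range(1, len(digs) + 1):
                cur = truth_rank(annotate(pl, digs[:k]))
                assert cur <= prev
                prev = cur

    def test_unresolved_when_no_composition(self):
        from glycanpipe.spectra import Peak, PeakList

        pl = PeakList([Peak(500.0)], precursor_mz=123.4)
        res = annotate(pl)
        assert res.tier == "unresolved"

    def test_conflicting_observation_reported_not_applied(
        self, galfuc_structure, noise_free_cfg
    ):
        rng = random.Random(5)
        pl = simulate_spectrum(galfuc_structure, noise_free_cfg, rng)
        digs = [DigestionObservation(1459, "nidulans-bgal", 1100)]
        res = annotate(pl, digs)
        assert res.conflicts
        assert res.annotations  # candidates were not silently discarded

    def test_equivalence_merging_of_indistinguishable_isomers(self, noise_free_cfg):
        # alpha-1,2-mannose placement isomers of Man7 that no fragment or
        # panel reagent separates collapse into one annotation
        s = parse_structure(
            "PA:GlcNAc(GlcNAc@b4(Man@b4(Man@a3(Man@a2),"
            "Man@a6(Man@a3,Man@a6(Man@a2)))))"
        )
        rng = random.Random(6)
        res, _, _ = _annotate_truth(s, noise_free_cfg, rng)
        top = res.annotations[0]
        assert len(top.structures()) >= 2
        assert any(
            x.mass_canonical() == s.mass_canonical() for x in top.structures()
        )

    def test_gu_bonus_requires_increment_table(self, galfuc_structure, noise_free_cfg):
        rng = random.Random(8)
        pl = simulate_spectrum(galfuc_structure, noise_free_cfg, rng)
        base = annotate(pl, gu=6.0)
        table = AnnotatorConfig(
            gu_increments={"Hex": 0.8, "HexNAc": 0.6, "Fuc": 0.4}
        )
        with_gu = annotate(pl, gu=6.0, cfg=table)
        assert base.annotations[0].score <= with_gu.annotations[0].score
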