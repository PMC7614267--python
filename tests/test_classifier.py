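"""Diagnostic-ion classification of MS/MS spectra."""

import random

import pytest

from glycanpipe import Composition, POSITIVE, classify_spectrum, pc_diagnostic
from glycanpipe.spectra import Peak, PeakList
from glycanpipe.synthetic import (
    SimulationConfig,
    reference_neutral_o_glycans,
    reference_pc_o_glycans,
    simulate_spectrum,
)
from glycanpipe import o_glycan_grammar


def _peaklist(mzs, precursor=None, polarity="positive"):
    return PeakList([Peak(m) for m in mzs], precursor_mz=precursor, polarity=polarity)


class TestClassifySpectrum:
    def test_pc_antenna_b_ions(self):
        comp = Composition.from_string("Hex3HexNAc3PC1", "PA")
        ev = classify_spectrum(comp, _peaklist([369.1, 531.2]), POSITIVE)
        motifs = ev.motifs(present=True)
        assert "antenna-PC-HexNAc" in motifs
        assert "antenna-Hex-HexNAc-PC" in motifs

    def test_linear_pc_chain_b_ions(self):
        comp = Composition.from_string("Hex3HexNAc6PC2", "PA")
        ev = classify_spectrum(comp, _peaklist([737.28, 940.36, 1143.44]), POSITIVE)
        motifs = ev.motifs(present=True)
        assert {"antenna-HexNAc2PC2", "antenna-HexNAc3PC2", "antenna-HexNAc4PC2"} <= motifs

    def test_empty_library_overlap(self):
        comp = Composition.from_string("Hex5HexNAc2", "PA")
        ev = classify_spectrum(comp, _peaklist([1000.0, 1100.0]), POSITIVE)
        assert ev.assertions == []

    def test_empty_spectrum_rejected(self):
        comp = Composition.from_string("Hex5HexNAc2", "PA")
        with pytest.raises(ValueError):
            classify_spectrum(comp, PeakList([]), POSITIVE)

    def test_composition_gate_blocks_impossible_ions(self):
        # a PC-free composition cannot give the m/z 369 PC-HexNAc B ion
        comp = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        ev = classify_spectrum(comp, _peaklist([369.14]), POSITIVE)
        assert "antenna-PC-HexNAc" not in ev.motifs()

    def test_largest_core_y1_wins(self):
        comp = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        ev = classify_spectrum(comp, _peaklist([446.21, 608.27]), POSITIVE)
        assert "proximal-state:F1G1" in ev.motifs(present=True)
        assert "proximal-state:F1G0" not in ev.motifs()

    def test_distal_galfuc_requires_608_absence(self):
        comp = Composition.from_string("Hex5HexNAc2Fuc2", "PA")
        with_608 = classify_spectrum(comp, _peaklist([811.35, 608.27]), POSITIVE)
        without = classify_spectrum(comp, _peaklist([811.35, 446.21]), POSITIVE)
        assert "distal-galfuc" not in with_608.motifs()
        assert "distal-galfuc" in without.motifs(present=True)

    def test_absence_assertion_for_unmodified_proximal(self):
        # fucosylated composition, but no fucosylated core Y1 observed
        comp = Composition.from_string("Hex4HexNAc2Fuc1", "PA")
        ev = classify_spectrum(comp, _peaklist([500.0, 800.0]), POSITIVE)
        unmod = [a for a in ev.assertions if a.motif == "proximal-unmodified"]
        assert len(unmod) == 1
        assert unmod[0].weight == pytest.approx(0.5)

    def test_reducing_galfuc_from_precursor_loss(self):
        comp = Composition.from_string("Hex5HexNAc2Fuc1", "PA")
        prec = 1459.56
        ev = classify_spectrum(
            comp, _peaklist([prec - 607.26], precursor=prec), POSITIVE
        )
        assert "reducing-galfuc" in ev.motifs(present=True)

    def test_intensity_floor_skips_traces_below_threshold(self):
        comp = Composition.from_string("Hex3HexNAc3PC1", "PA")
        pl = PeakList([Peak(369.14, 0.001), Peak(800.0, 1.0)])
        ev = classify_spectrum(comp, pl, POSITIVE)
        assert "antenna-PC-HexNAc" not in ev.motifs()

    def test_noise_peaks_leave_evidence_unchanged(self):
        comp = Composition.from_string("Hex3HexNAc3PC1", "PA")
        base = _peaklist([369.14, 531.2])
        ev0 = [(a.motif, a.present) for a in classify_spectrum(comp, base, POSITIVE).assertions]
        rng = random.Random(4)
        for _ in range(10):
            noise = [
                Peak(rng.uniform(150, 2500), rng.uniform(0.02, 0.4))
                for _ in range(8)
            ]
            # keep noise away from any library m/z to stay off-diagnostic
            noise = [
                p
                for p in noise
                if not any(abs(p.mz - lib) < 1.0 for lib in
                           (369.1, 531.2, 446.2, 592.3, 608.3, 754.3, 770.3,
                            916.4, 811.3, 407.2, 572.2, 737.3, 775.3, 940.4,
                            978.4, 1143.4, 734.3, 899.3, 937.4, 1102.4,
                            1140.4, 1305.5))
            ]
            pl = PeakList(base.peaks + noise)
            ev = classify_spectrum(comp, pl, POSITIVE)
            assert [(a.motif, a.present) for a in ev.assertions] == ev0


class TestPcDiagnostic:
    def test_simulated_pc_o_glycans_flagged(self):
        cfg = SimulationConfig(
            seed=9, n_structures=1, grammar=o_glycan_grammar(),
            mz_sigma=0.05, dropout=0.1, spurious_rate=0.0,
        )
        rng = random.Random(9)
        for s in reference_pc_o_glycans():
            pl = simulate_spectrum(s, cfg, rng)
            assert pc_diagnostic(pl, pl.precursor_mz)

    def test_neutral_o_glycans_not_flagged(self):
        cfg = SimulationConfig(
            seed=9, n_structures=1, grammar=o_glycan_grammar(),
            mz_sigma=0.05, dropout=0.1, spurious_rate=0.0,
        )
        rng = random.Random(10)
        for s in reference_neutral_o_glycans():
            pl = simulate_spectrum(s, cfg, rng)
            assert not pc_diagnostic(pl, pl.precursor_mz)
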