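# glycanpipe

Structural annotation of nematode N- and O-glycans from MALDI-TOF MS/MS and
LC–ESI–MS peak lists.

*Caenorhabditis elegans* decorates a small chitobiose/mannose N-glycan core
with an unusually rich set of modifications: up to three core fucoses
(α1,3/α1,6 on the proximal GlcNAc, α1,3 on the distal GlcNAc), α- or
β-galactose caps on those fucoses ("GalFuc"), a bisecting β1,4-galactose on
the core β-mannose that may itself carry (methylated) α1,2-fucose, α-Gal on
the α1,3-mannose, and HexNAc-based antennae substituted with
phosphorylcholine (PC). Reduced mucin-type O-glycans add hexuronic acid and
PC-modified chains. Mass spectrometry alone cannot separate the many
isomers a single composition admits; in practice structures are assigned by
combining four kinds of evidence: the masses of the component
monosaccharides, mass differences within glycan series, fragmentation
patterns, and shifts after exoglycosidase or hydrofluoric-acid treatment.

`glycanpipe` turns that manual reasoning into a tested pipeline:

1. **Composition assignment** — the precursor m/z is matched against the
   bounded lattice `Hex_a HexNAc_b Fuc_c (HexA_d) Me_e PC_f` (±0.25 Da,
   configurable); grammar-feasible compositions rank first and isobaric
   ambiguity is surfaced, never silently resolved.
2. **Candidate enumeration** — all structures a motif grammar of the
   *C. elegans* glycome admits for that composition (tetra-antennary and
   anionic N-glycans excluded; decorations follow Golgi processing order).
3. **Fragment evidence** — diagnostic ions from an editable library: core
   Y1 ions (m/z 446/592/608/754/770/916 report the proximal substitution
   state; the largest consistent ion wins), the Y2 at 811 with the 608
   absent for a distal GalFuc, PC-antenna B ions (369, 531, 572/737/940/
   1143, 734/899/937/1102/1305), LacdiNAc at 407, precursor neutral losses,
   and the negative-mode [M−H−59] trimethylamine loss that flags PC.
4. **Digestion reasoning** — a reagent panel (two β-galactosidases with
   different reach, coffee-bean α-galactosidase, α1,2-fucosidase, HEX-4,
   jack-bean hexosaminidase and mannosidase, an α1,2/3-restricted
   mannosidase, chitinase, PC esterase, hydrofluoric acid) is applied
   in silico to every candidate; candidates that cannot reproduce an
   observed before/after mass shift are eliminated.
5. **Scoring** — supported assertions add weight (presence 1.0, absence
   0.5, digestion consistency 2.0 per reagent, glucose-unit class 0.5),
   conflicts subtract 3.0, and a bounded fragmentation-pattern concordance
   term separates topological isomers. Candidates that no fragment or
   panel reagent could distinguish even in principle are reported as one
   annotation.
6. **Retention calibration** — retention times map to glucose units (g.u.)
   by piecewise-linear interpolation of a dextran-ladder calibration.

A seeded synthetic-data generator (grammar-sampled structures, simulated
MS/MS spectra with jitter/dropout/spurious peaks, simulated digestion
experiments) makes every stage testable end to end without any instrument
data.

## Worked example

Simulate the MS/MS spectrum of the Hex5HexNAc2Fuc1 isoform carrying the
GalFuc epitope on the proximal GlcNAc (label m/z 1459) together with a
four-reagent digestion experiment, then annotate:

```sh
glycanpipe match --peaks galfuc.tsv
# mz      rank  composition      delta_mDa
# 1459.5568  1  Hex5HexNAc2Fuc1  0.0

glycanpipe classify --peaks galfuc.tsv
# composition: Hex5HexNAc2Fuc1
# assertion: proximal-state:F1G1 (source: Y1 608, weight 1.0)
# assertion: reducing-galfuc (source: precursor loss 607, weight 1.0)

cat digests.tsv
# parent_mz  reagent        product_mz
# 1459       nidulans-bgal  1297
# 1459       hf             1459
# 1459       a23-man        1135
# 1459       jackbean-man   973

glycanpipe annotate --peaks galfuc.tsv --digests digests.tsv --out report.txt
# tier: unique; report written to report.txt
```

The report names the recovered structure and the evidence trail:

```
composition: Hex5HexNAc2Fuc1
tier: unique
evidence: proximal-state:F1G1 (present, Y1 608, w=1.0)
evidence: reducing-galfuc (present, precursor loss 607, w=1.0)
candidate[1] score=11.920 PA:GlcNAc(Fuc@a6(Gal@b4),GlcNAc@b4(Man@b4(Man@a3,Man@a6(Man@a3))))
```

Reading the evidence: the Y1 fragment at m/z 608 (Gal1Fuc1GlcNAc1-PA) puts
one galactosylated fucose on the proximal GlcNAc; β-galactosidase removes
one hexose (1459 → 1297), confirming a β-Gal on the core α1,6-fucose;
HF resistance excludes an α1,3-linked core fucose; and the two mannosidase
products pin the Man4 arm topology. Fifty-four alternative candidates are
eliminated or outscored, and the eliminations are listed in the report.

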