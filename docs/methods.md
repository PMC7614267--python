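# Methods

## Data model

Glycans are rooted trees of monosaccharide residues. Because MS cannot
distinguish epimers, residues are typed by mass class — Hex (162.0528 Da,
covering Man/Gal/Glc), HexNAc (203.0794, GlcNAc/GalNAc), Fuc (146.0579),
HexA (176.0321) — with substituents Me (+14.0157) and PC (+165.0555). Each
node may carry an *identity* tag (`Man` vs `Gal`, `GlcNAc` vs `GalNAc`)
that is pure metadata: the mass engine ignores it and only reagent
specificity rules (HEX-4 vs jack-bean hexosaminidase, α- vs β-
galactosidase, mannosidases) consult it. Where the identity of a terminal
antennal HexNAc is not determined by the grammar slot, candidate
enumeration leaves it unknown and epimer-dependent reagents treat both
outcomes as admissible, so unknown identity can never falsely eliminate a
candidate. Linkage fields (anomer, position) are tri-state: known values
are those the grammar defines; evidence may upgrade unknown to known but
never overwrite.

The reducing end carries the label state: pyridylaminated (+78.0582 Da,
N-glycans, measured as [M+H]+), reduced alditol (+2.0157 Da, O-glycans,
measured as [M−H]−), or free. Neutral mass = residue sum + substituents +
water (18.0106) + label. Printed integer labels truncate (floor) the
monoisotopic m/z: 1637.60 → 1637 and 2235.85 → 2235, which plain rounding
would both get wrong.

## Fragmentation

Glycosidic B/Y (and, in negative mode, Z = Y − H2O) ions follow the
Domon–Costello convention with B as the oxocarbenium (residue sum + proton
in positive mode, − proton in negative). Single charge only. Double cuts
yield internal fragments (nested cuts, B-like) and doubly truncated Y
ions. Negative-mode extras: every PC-containing fragment and the precursor
gain a −59.0735 Da trimethylamine-loss variant, and Y/Z ions retaining a
hexuronic acid that is subterminal in the parent structure gain a −43.9898
Da CO2-loss variant. Cross-ring (A/X) fragments and isotope patterns are
not modelled. For every single cut, B + Y reconstructs the protonated
precursor plus one proton exactly — an invariant the tests enforce at
0.01 Da over a 500-structure panel.

## Motif grammar

The N-glycan candidate space is bounded by a grammar of the *C. elegans*
repertoire:

* chitobiose core (proximal + distal GlcNAc) with a mannose scaffold that
  is a connected subset of the canonical Man9 tree containing the
  β-mannose; α1,2-mannoses are only admitted on a complete Man5 base (the
  mannosidase processing series), which gives 21 scaffolds in total and a
  unique topology for Man5 and Man9;
* proximal GlcNAc optionally α1,3- and/or α1,6-fucosylated; distal GlcNAc
  optionally α1,3-fucosylated; β1,4-Gal (optionally extended by a second
  β-Gal) on the α1,6-fucose; a single terminal α-Gal on either
  α1,3-fucose;
* bisecting β1,4-Gal on the β-mannose, optionally carrying α1,2-fucose
  that may be methylated (the only methylation site in the default
  grammar);
* α-Gal on the α1,3-mannose;
* at most three antennae: linear β-linked HexNAc chains (length 1–4) on
  the arm mannoses, at most two per arm (β1,2 slot first, then β1,4), with
  at most two PC groups on chain HexNAcs. An arm mannose with two chains
  is the branched Hex1HexNAc2–4 unit seen as B ions at m/z 734–1305.

Tetra-antennary and anionic (HexA-containing) N-glycans are excluded.
Decorations (core fucoses, bisect, α-Gal, antennae) additionally require
an α1,2-trimmed scaffold, reflecting Golgi processing order (mannosidase I
and the GnT-I-dependent steps precede fucosylation and antenna synthesis);
this also removes chemically meaningless candidates such as fucosylated
Man9.

Three symmetry conventions make enumeration exhaustive *up to what MS can
see* — in each case the swapped variant has identical fragment masses, so
both forms would be pure double counting:

* when both arm mannoses are chain-eligible, the canonically larger chain
  group sits on the α1,3 arm;
* a solitary chain-bearing unextended arm is the α1,3 arm;
* of two chains on one mannose, the larger occupies the β1,2 slot.

The sampler and the enumerator build trees through the same constructors,
so every sampled ground-truth structure is guaranteed to lie in the
enumerated candidate set. An independent test oracle grows trees residue
by residue through grammar-valid states and reproduces the enumerator's
candidate sets exactly on small compositions.

The O-glycan grammar is deliberately small: a GalNAc alditol core with an
optional core-1 galactose branch (±α-fucose, ≤2 extending hexoses) and one
linear chain of HexNAc (±PC) and HexA units with an optional hexose cap.
Methylation is excluded in O-glycan mode (none is modelled), which also
removes the 36-mDa Hex+Me vs HexA near-isobar from the composition
lattice.

## Composition matching

Complete enumeration of the bounded lattice (defaults: Hex ≤ 9,
HexNAc ≤ 8, Fuc ≤ 5, Me ≤ 2, PC ≤ 2; HexA ≤ 2 only in O-glycan mode)
within ±0.25 Da of the observed precursor — the observed deviations are
typically 0.1–0.2 Da, plus margin. Ranking: grammar-feasible compositions
(those admitting at least one candidate structure) first, then by 0.1-Da
deviation band, then by fewer distinct residue classes, then by exact
|Δm|. The band-then-parsimony order reflects annotation practice: within
the instrument's typical deviation, a 5-class interpretation such as
HexNAc4Fuc1Me1 (74 mDa from Hex6) does not beat a plain oligomannose
assignment. All lattice members within tolerance remain listed, so real
ambiguity is always visible.

## Digestion reasoning

Reagent specificities are combinations of primitives applied to candidate
trees to exhaustion (e.g. *A. nidulans* β-galactosidase reaches only the
galactose chain on the core α1,6-fucose; *A. niger* additionally removes a
terminal bisecting galactose unless the distal GlcNAc is substituted; HF
excises α1,3-fucoses together with their galactose caps, removes PC, and
removes the bisect (methyl)fucose only partially; jack-bean hexosaminidase
spares terminal HexNAc inside PC-modified chains). Partial chemistry and
epimer-unknown removals are *admissible* rather than mandatory, so the
predicted product set contains every intermediate a partial digest could
show. A candidate survives an observation when the observed product label
is in its predicted set; an observation that eliminates every remaining
candidate is flagged as an evidence conflict and not applied. The panel
ships as editable YAML; new reagents can be composed from the primitives
without code changes.

## Scoring and annotation

score = Σ weight(supported assertions) − 3.0 · conflicts
      + Σ reagent weight (2.0 by default) per consistent digestion
      + 0.5 glucose-unit class bonus (only when the user supplies an
        increment table; none is shipped)
      + 2.0 · fragment-concordance, a tolerance-matched Jaccard overlap
        between the observed MS/MS peaks and the candidate's theoretical
        fragments.

Presence assertions carry the diagnostic m/z (or neutral-loss mass); a
candidate conflicts only when its theoretical fragments cannot produce the
diagnostic peak. This matters because several printed diagnostics are
mass-degenerate: the Y2 at m/z 811 (GlcNAc2Fuc1Gal1-PA) coincides exactly
with loss of one hexose from a Hex2HexNAc2Fuc1 precursor, and the −607
GalFuc loss with certain internal fragments. Absence assertions (an
unmodified proximal GlcNAc inferred from missing fucosylated Y1 ions)
carry half weight, and are only made when the precursor composition makes
the missing ion possible. The fragment-concordance term implements the
"fragmentation patterns" criterion and is what separates topological
isomers whose diagnostic ions coincide (e.g. which mannose branch carries
an extension).

Score-tied candidates that are indistinguishable *in principle* — same
theoretical fragment m/z multiset and same product labels under every
reagent of the panel — are merged into a single annotation (α1,2-mannose
placement isomers of Man6–8 are the main case; in practice only
chromatographic retention separates them). Remaining exact ties are
reported as the `ambiguous` confidence tier; `unresolved` marks precursors
with no assignable composition or no surviving candidate. Tie-breaking
for equal scores is fewer unknown linkages, then lexicographic
serialization — stable, declared, arbitrary. Identical input and
configuration give byte-identical reports.

Glucose units enter only as a coarse class bonus: retention is used
comparatively in this workflow, and no per-residue increment table is
printed anywhere authoritative, so any increments are user-supplied.

## Synthetic data

The generator emulates the statistical shape of a nematode N-glycome:
paucimannosidic/core-modified structures dominate; the mannose count is
drawn with weights (1: 0.03, 2: 0.10, 3: 0.30, 4: 0.12, 5: 0.20, 6–8:
0.05 each, 9: 0.10), Man5 being the most abundant oligomannosidic form;
core α1,3-/α1,6-fucosylation at 0.35/0.40, distal fucosylation rare
(0.08); galactose caps, bisect (±fucose ± methyl) and α-Gal at moderate
rates; antennae on 35 % of eligible structures with PC on roughly half.
A default 500-structure run exercises every grammar motif (a tested
coverage guarantee). Sampled compositions stay inside the matcher bounds.

Spectra are the exhaustive two-cut fragment set plus the residual
precursor ion, with additive Gaussian m/z jitter (σ = 0.05 Da by default,
matching the 0.1–0.2 Da typical deviations), uniform fragment dropout
(0.1) and Poisson-distributed uniform spurious peaks (mean 5 per
spectrum). The [M−H−59] PC diagnostic peak is never dropped by default —
it is the peak the negative-mode workflow keys on; this is configurable.
No intensity realism is attempted. Digestion observations report one
admissible product per reagent (a seeded random choice among
intermediates for partial reagents).

What passing tests show — and what they do not: the synthetic spectra
have exact theoretical peak positions, complete fragment coverage (up to
dropout), and digestion products drawn from the model's own predictions,
so the end-to-end recovery rates certify the *inference logic* (grammar
completeness, evidence extraction, elimination and ranking), not
robustness to real instrument artifacts (isotope envelopes, in-source
decay, intensity effects, co-eluting precursors).

## Numerical and problem-size choices

Fragment matching uses ±0.3 Da on raw m/z and exact equality on integer
labels; composition matching ±0.25 Da; B/Y complementarity 0.01 Da. The
enumeration cap is 10,000 candidates with an explicit truncation flag.
The test suite and the acceptance script use 500-structure panels for the
complementarity, matcher, digestion and recovery experiments, 100 random
masses for the lattice-oracle comparison, and 150 spectra per arm of the
PC-diagnostic check; these sizes give stable percentages (binomial s.e.
≈ 1 % at p = 0.95) while keeping a full run in tens of seconds. The PC
diagnostic is evaluated with jitter and dropout but without spurious
peaks: a spurious peak landing exactly at [M−H−59] is indistinguishable
from the diagnostic by construction, so specificity is defined against
chemical peaks.

## Known limitations

* Epimer identity and linkage beyond the grammar's defined slots are not
  inferred, only carried; a LacdiNAc vs chito-chain terminus is resolved
  only when HEX-4/jack-bean evidence is supplied.
* α1,2-mannose placement isomers (Man6–8) are indistinguishable to every
  evidence source modelled here and are reported as one merged
  annotation; separating them needs retention data.
* Quantification, relative abundances between samples, deisotoping and
  multiply charged species are out of scope.
* The O-glycan grammar covers the core-1/PC/HexA space needed for the
  negative-mode diagnostics, not the full mucin-type repertoire.
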