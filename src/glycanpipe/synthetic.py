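"""Synthetic ground-truth structures, spectra and digestion experiments.

The generator emulates the statistical shape of a nematode glycome dataset
so every pipeline stage is testable without any download: paucimannosidic
and core-modified structures dominate, oligomannosidic structures are
common (Man5 most abundant), phosphorylcholine-bearing antennae appear on a
minority of complex/hybrid structures, and distal-arm or LacdiNAc motifs
are rare -- frequent enough that a default 500-structure run exercises
every grammar motif.

Noise model: additive Gaussian m/z jitter (default sigma 0.05 Da, matching
typical 0.1-0.2 Da observed deviations), uniform spurious peaks over the
scan range, and uniform fragment dropout. The negative-mode [M-H-59]
trimethylamine-loss peak of PC glycans is never dropped by default (it is
the diagnostic the O-glycan workflow relies on); disable via
``keep_pc_diagnostic``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .digestion import (
    DigestionObservation,
    ReagentSpec,
    default_panel,
    predict_products,
    structure_label,
)
from .enumeration import (
    AntennaChain,
    NGlycanChoices,
    OGlycanChoices,
    build_n_glycan,
    build_o_glycan,
)
from .masses import NEGATIVE, POSITIVE, IonMode, enumerate_fragments, precursor_mz
from .model import (
    GlycanStructure,
    MotifGrammar,
    composition_of,
    match_motifs,
    mannose_scaffolds,
    n_glycan_grammar,
)
from .spectra import Peak, PeakList

__all__ = [
    "SimulationConfig",
    "sample_structures",
    "simulate_spectrum",
    "simulate_digestion",
    "reference_pc_o_glycans",
    "reference_neutral_o_glycans",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded simulation parameters; a given seed fixes all outputs."""

    seed: int = 0
    n_structures: int = 500
    grammar: MotifGrammar = field(default_factory=n_glycan_grammar)
    mz_sigma: float = 0.05  # Da
    spurious_rate: float = 5.0  # expected spurious peaks per spectrum
    dropout: float = 0.1  # fragment dropout probability
    keep_pc_diagnostic: bool = True
    max_cuts: int = 2
    #: composition bounds the matcher uses; sampled structures stay inside
    max_hex: int = 9
    max_hexnac: int = 8
    max_fuc: int = 5

    def __post_init__(self) -> None:
        if self.mz_sigma < 0:
            raise ValueError("mz_sigma must be >= 0")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be a probability")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")


# ---------------------------------------------------------------------------
# structure sampling
# ---------------------------------------------------------------------------

#: probability of the mannose count, paucimannose-dominant with Man5 the
#: most abundant oligomannosidic form
_MAN_COUNT_WEIGHTS = {
    1: 0.03, 2: 0.10, 3: 0.30, 4: 0.12, 5: 0.20,
    6: 0.05, 7: 0.05, 8: 0.05, 9: 0.10,
}


def _weighted(rng: random.Random, table: dict) -> object:
    r = rng.random() * sum(table.values())
    acc = 0.0
    for k, w in table.items():
        acc += w
        if r <= acc:
            return k
    return k  # numeric edge


def _sample_chain(rng: random.Random, grammar: MotifGrammar) -> AntennaChain:
    length = _weighted(rng, {1: 0.45, 2: 0.25, 3: 0.20, 4: 0.10})
    length = min(length, grammar.max_chain_len)
    terminal = None
    if length >= 2:
        terminal = "GalNAc" if rng.random() < 0.25 else "GlcNAc"
    return AntennaChain(length, frozenset(), terminal)


def _sample_n_choices(rng: random.Random, grammar: MotifGrammar) -> NGlycanChoices:
    by_size: dict[int, list] = {}
    for s in mannose_scaffolds(grammar.max_man):
        if len(s) >= grammar.min_man:
            by_size.setdefault(len(s), []).append(s)
    k = _weighted(rng, {k: w for k, w in _MAN_COUNT_WEIGHTS.items() if k in by_size})
    scaffold = rng.choice(by_size[k])

    def allow(flag: bool, p: float) -> bool:
        return flag and rng.random() < p

    from .model import ALPHA2_KEYS

    trimmed = not (grammar.trimmed_decorations and scaffold & ALPHA2_KEYS)
    prox_a3 = trimmed and allow(grammar.allow_core_a3_fuc, 0.35)
    prox_a6 = trimmed and allow(grammar.allow_core_a6_fuc, 0.40)
    distal_fuc = trimmed and allow(grammar.allow_distal_a3_fuc, 0.08)
    prox_a3_gal = prox_a3 and allow(grammar.allow_galfuc, 0.20)
    a6_gal = 0
    if prox_a6 and allow(grammar.allow_galfuc, 0.35):
        a6_gal = 2 if rng.random() < 0.15 else 1
    distal_gal = distal_fuc and allow(grammar.allow_galfuc, 0.30)
    bisect: Optional[str] = None
    if trimmed and allow(grammar.allow_bisect, 0.25):
        bisect = "Gal"
        if rng.random() < 0.40:
            bisect = "GalFucMe" if rng.random() < 0.40 else "GalFuc"
    agal = (
        trimmed
        and "a3" in scaffold
        and "a3.2" not in scaffold
        and allow(grammar.allow_agal_man, 0.12)
    )
    base = NGlycanChoices(
        scaffold=scaffold,
        prox_a3=prox_a3,
        prox_a3_gal=prox_a3_gal,
        prox_a6=prox_a6,
        a6_gal=a6_gal,
        distal_fuc=distal_fuc,
        distal_gal=distal_gal,
        bisect=bisect,
        agal_a3=agal,
    )
    from .enumeration import arm_eligibility

    a3_ok, a6_ok = arm_eligibility(base)
    if not trimmed:
        a3_ok = a6_ok = False
    chains: list[AntennaChain] = []
    if grammar.allow_antennae and (a3_ok or a6_ok) and rng.random() < 0.35:
        n_chains = _weighted(rng, {1: 0.55, 2: 0.30, 3: 0.15})
        n_chains = min(n_chains, (2 if a3_ok else 0) + (2 if a6_ok else 0),
                       grammar.max_antennae)
        chains = [_sample_chain(rng, grammar) for _ in range(n_chains)]
        # PC placement over all chain positions
        n_pc = _weighted(rng, {0: 0.45, 1: 0.35, 2: 0.20})
        positions = [
            (ci, pos) for ci, c in enumerate(chains) for pos in range(c.length)
        ]
        n_pc = min(n_pc, grammar.max_pc, len(positions))
        for ci, pos in rng.sample(positions, n_pc):
            c = chains[ci]
            chains[ci] = AntennaChain(c.length, c.pc | {pos}, c.terminal)
    # distribute chains over eligible arms (canonicalized by the builder)
    g3: list[AntennaChain] = []
    g6: list[AntennaChain] = []
    for c in chains:
        targets = []
        if a3_ok and len(g3) < 2:
            targets.append(g3)
        if a6_ok and len(g6) < 2:
            targets.append(g6)
        rng.choice(targets).append(c)
    return replace(base, chains_a3=tuple(g3), chains_a6=tuple(g6))


def _sample_o_choices(rng: random.Random, grammar: MotifGrammar) -> OGlycanChoices:
    core1 = rng.random() < 0.8
    core1_fuc = core1 and rng.random() < 0.3
    core1_ext = _weighted(rng, {0: 0.6, 1: 0.25, 2: 0.15}) if core1 else 0
    chain_len = _weighted(rng, {0: 0.30, 1: 0.25, 2: 0.25, 3: 0.20})
    tokens: list[str] = []
    hexa = pc = 0
    for _ in range(chain_len):
        if hexa < grammar.max_hexa and rng.random() < 0.20:
            tokens.append("HexA")
            hexa += 1
        elif pc < grammar.max_pc and rng.random() < 0.35:
            tokens.append("HexNAc+PC")
            pc += 1
        else:
            tokens.append("HexNAc")
    cap_hex = bool(tokens) and rng.random() < 0.2
    return OGlycanChoices(core1, core1_fuc, core1_ext, tuple(tokens), cap_hex)


def sample_structures(
    cfg: SimulationConfig,
) -> list[tuple[GlycanStructure, dict]]:
    """Sample ``cfg.n_structures`` grammar-valid ground-truth structures.

    Deterministic per seed. Each structure comes with a truth record
    (spectrum id, serialized structure, composition, motif list).
    """
    rng = random.Random(cfg.seed)
    grammar = cfg.grammar
    out: list[tuple[GlycanStructure, dict]] = []
    attempts = 0
    while len(out) < cfg.n_structures:
        attempts += 1
        if attempts > 100 * cfg.n_structures:
            raise RuntimeError("grammar constraints appear unsatisfiable")
        if grammar.mode == "N":
            structure = build_n_glycan(_sample_n_choices(rng, grammar))
        else:
            structure = build_o_glycan(_sample_o_choices(rng, grammar))
        comp = composition_of(structure)
        if (
            comp.hex > cfg.max_hex
            or comp.hexnac > cfg.max_hexnac
            or comp.fuc > cfg.max_fuc
        ):
            continue
        sid = f"sim-{len(out):04d}"
        record = {
            "spectrum_id": sid,
            "structure": structure.serialize(),
            "composition": str(comp),
            "motifs": sorted({name for name, _ in match_motifs(structure, grammar)}),
        }
        out.append((structure, record))
    return out


# ---------------------------------------------------------------------------
# spectrum simulation
# ---------------------------------------------------------------------------


def _mode_for(structure: GlycanStructure) -> IonMode:
    return NEGATIVE if structure.label_state == "alditol" else POSITIVE


def simulate_spectrum(
    s: GlycanStructure,
    cfg: SimulationConfig,
    rng: Optional[random.Random] = None,
    spectrum_id: Optional[str] = None,
) -> PeakList:
    """Theoretical fragments + precursor, with jitter/dropout/spurious noise.

    With sigma = 0, dropout = 0 and spurious_rate = 0 the peak set equals
    the theoretical fragment set exactly.
    """
    rng = rng or random.Random(cfg.seed)
    mode = _mode_for(s)
    comp = composition_of(s)
    prec = precursor_mz(comp, mode)
    frags = enumerate_fragments(s, mode, cfg.max_cuts)
    peaks: list[Peak] = []
    prec_jitter = rng.gauss(0.0, cfg.mz_sigma) if cfg.mz_sigma > 0 else 0.0
    peaks.append(Peak(prec + prec_jitter, 1.0))  # residual precursor ion
    for f in frags:
        protected = (
            cfg.keep_pc_diagnostic
            and f.kind == "precursor"
            and "trimethylamine" in f.losses
        )
        if not protected and cfg.dropout > 0 and rng.random() < cfg.dropout:
            continue
        mz = f.mz + (rng.gauss(0.0, cfg.mz_sigma) if cfg.mz_sigma > 0 else 0.0)
        if mz > 0:
            peaks.append(Peak(mz, 1.0))
    if cfg.spurious_rate > 0:
        n_spurious = _poisson(rng, cfg.spurious_rate)
        lo, hi = 150.0, prec + 50.0
        for _ in range(n_spurious):
            peaks.append(Peak(rng.uniform(lo, hi), rng.uniform(0.02, 0.2)))
    prec_obs = prec + prec_jitter
    peaks.sort(key=lambda p: p.mz)
    return PeakList(
        peaks,
        precursor_mz=prec_obs,
        polarity=mode.polarity,
        spectrum_id=spectrum_id,
    )


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lambda is small (a handful of spurious peaks)
    import math

    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


# ---------------------------------------------------------------------------
# digestion simulation
# ---------------------------------------------------------------------------


def simulate_digestion(
    s: GlycanStructure,
    panel: Optional[dict[str, ReagentSpec]] = None,
    reagents: Optional[list[str]] = None,
    cfg: Optional[SimulationConfig] = None,
    rng: Optional[random.Random] = None,
) -> list[DigestionObservation]:
    """Observed before/after labels for each panel reagent.

    Complete reagents report a terminal product; partial reagents (and
    removals that are admissible rather than mandatory) report a randomly
    chosen admissible product, seeded via the config.
    """
    panel = panel or default_panel()
    names = reagents if reagents is not None else list(panel)
    rng = rng or random.Random(cfg.seed if cfg else 0)
    parent_label = structure_label(s)
    out = []
    for name in names:
        reagent = panel[name]
        products = predict_products(s, reagent)
        product = rng.choice(products)
        out.append(DigestionObservation(parent_label, name, product[1]))
    return out


# ---------------------------------------------------------------------------
# reference O-glycan panels (synthetic reconstructions)
# ---------------------------------------------------------------------------


def reference_pc_o_glycans() -> list[GlycanStructure]:
    """Synthetic reconstructions of five phosphorylcholine-modified
    mucin-type O-glycans of *C. elegans* (reduced alditols, negative mode):
    HexNAc2HexA1PC1 with subterminal or terminal hexuronic acid ([M-H]- at
    m/z 766), its HexNAc- and Hex-extended forms (m/z 969; [M+H]+ 930), and
    a HexNAc2PC2-terminated form."""
    return [
        # GalNAc-ol <- HexA <- GlcNAc(+PC): subterminal HexA, m/z 766
        build_o_glycan(OGlycanChoices(chain=("HexA", "HexNAc+PC"))),
        # GalNAc-ol <- GlcNAc(+PC) <- HexA: nonreducing terminal HexA, m/z 766
        build_o_glycan(OGlycanChoices(chain=("HexNAc+PC", "HexA"))),
        # GalNAc-ol <- HexA <- GlcNAc(+PC) <- GlcNAc: m/z 969
        build_o_glycan(OGlycanChoices(chain=("HexA", "HexNAc+PC", "HexNAc"))),
        # GalNAc-ol <- HexA <- GlcNAc(+PC) <- Hex cap: linear, [M+H]+ 930
        build_o_glycan(OGlycanChoices(chain=("HexA", "HexNAc+PC"), cap_hex=True)),
        # core-1 Gal branch plus a HexNAc2PC2 chain terminus
        build_o_glycan(
            OGlycanChoices(core1=True, chain=("HexNAc+PC", "HexNAc+PC"))
        ),
    ]


def reference_neutral_o_glycans() -> list[GlycanStructure]:
    """PC-free mucin-type O-glycans (core-1 based) for specificity checks."""
    return [
        build_o_glycan(OGlycanChoices(core1=True)),
        build_o_glycan(OGlycanChoices(core1=True, core1_fuc=True, core1_ext=1)),
        build_o_glycan(OGlycanChoices(core1=True, core1_ext=2)),
        build_o_glycan(OGlycanChoices(core1=True, chain=("HexNAc",))),
        build_o_glycan(OGlycanChoices(core1=True, core1_fuc=True, chain=("HexNAc", "HexA"))),
    ]
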