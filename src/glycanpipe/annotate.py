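"""Top-level structural inference: enumerate grammar-consistent candidates
for an assigned composition and rank them against the combined evidence.

The evidential hierarchy mirrors manual annotation practice: digestion
shifts outrank fragment diagnostics, which outrank retention (glucose-unit)
class; a bounded fragmentation-pattern concordance term (tolerance-matched
Jaccard overlap between observed MS/MS peaks and a candidate's theoretical
fragments) separates topological isomers whose diagnostic ions coincide.
All weights are configurable; identical inputs, configuration and seed give
byte-identical ranked output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .diagnostics import (
    Assertion,
    ClassifierConfig,
    EvidenceSet,
    classify_spectrum,
)
from .digestion import (
    DigestionObservation,
    ReagentSpec,
    default_panel,
    interpret_shift,
)
from .enumeration import enumerate_candidates
from .masses import IonMode, enumerate_fragments, precursor_mz
from .matcher import CompositionCandidate, MatcherConfig, match_composition
from .model import Composition, GlycanStructure, MotifGrammar, composition_of
from .spectra import PeakList

__all__ = [
    "AnnotatorConfig",
    "Annotation",
    "AnnotationResult",
    "annotate",
    "candidate_supports",
    "score_candidates",
]


@dataclass(frozen=True)
class AnnotatorConfig:
    """Scoring weights and enumeration limits for annotation."""

    conflict_penalty: float = 3.0
    gu_weight: float = 0.5
    gu_tolerance: float = 0.5
    spectrum_weight: float = 2.0  # fragmentation-pattern concordance (bounded)
    fragment_tolerance: float = 0.3
    enumeration_cap: int = 10_000
    max_cuts: int = 2
    #: optional per-residue-class glucose-unit increments (user-supplied;
    #: none shipped -- retention enters only as a coarse class bonus)
    gu_base: float = 2.0
    gu_increments: Optional[dict] = None


@dataclass
class Annotation:
    """One ranked candidate with its per-evidence support trail.

    ``equivalent`` lists further structures that are indistinguishable from
    ``structure`` *in principle* at this evidence level: identical
    theoretical fragment sets and identical product labels under every
    reagent of the panel. Such structures form a single annotation at the
    resolution the assay supports (e.g. alpha-1,2-mannose placement isomers
    that only chromatography separates).
    """

    structure: GlycanStructure
    score: float
    rank: int
    support: list[tuple[str, str]] = field(default_factory=list)  # (assertion, verdict)
    digestion_bonus: float = 0.0
    spectrum_score: float = 0.0
    equivalent: list[GlycanStructure] = field(default_factory=list)

    def structures(self) -> list[GlycanStructure]:
        return [self.structure, *self.equivalent]


@dataclass
class AnnotationResult:
    composition: Optional[Composition]
    composition_candidates: list[CompositionCandidate]
    annotations: list[Annotation]
    tier: str  # "unique" | "ambiguous" | "unresolved"
    evidence: Optional[EvidenceSet] = None
    eliminated: list[tuple[str, str]] = field(default_factory=list)  # (structure, reason)
    conflicts: list[str] = field(default_factory=list)
    truncated: bool = False
    reason: Optional[str] = None


# ---------------------------------------------------------------------------
# assertion support
# ---------------------------------------------------------------------------


def _proximal_state(s: GlycanStructure) -> tuple[int, int]:
    """(fucose count, galactose count) on/under the proximal GlcNAc."""
    fucs = [c for c in s.root.children if c.residue == "Fuc"]
    gals = 0
    for f in fucs:
        stack = list(f.children)
        while stack:
            n = stack.pop()
            if n.residue == "Hex":
                gals += 1
            stack.extend(n.children)
    return len(fucs), gals


def _distal_galfuc(s: GlycanStructure) -> bool:
    distal = next((c for c in s.root.children if c.residue == "HexNAc"), None)
    if distal is None:
        return False
    for f in (c for c in distal.children if c.residue == "Fuc"):
        if any(g.residue == "Hex" for g in f.children):
            return True
    return False


def candidate_supports(
    structure: GlycanStructure,
    assertion: Assertion,
    fragments,
    precursor: Optional[float] = None,
    tolerance: float = 0.3,
) -> bool:
    """Is the candidate structure consistent with the asserted evidence?

    Diagnostic-ion assertions carry the diagnostic m/z (or precursor
    neutral-loss mass): a candidate supports the assertion iff its
    theoretical fragment set can produce the diagnostic peak. Structural
    absence assertions (unmodified proximal GlcNAc) and composition-level
    assertions (PC glycan) are checked on the tree directly. Diagnostics
    whose m/z is mass-degenerate with other fragments (e.g. the Y2 at m/z
    811 vs loss of one hexose) therefore never falsely conflict.
    """
    motif = assertion.motif
    if motif == "proximal-unmodified":
        return _proximal_state(structure)[0] == 0
    if motif == "pc-glycan":
        return composition_of(structure).pc > 0
    if assertion.loss is not None:
        if precursor is None:
            return True
        target = precursor - assertion.loss
        return any(abs(f.mz - target) <= tolerance for f in fragments)
    if assertion.mz is not None:
        return any(abs(f.mz - assertion.mz) <= tolerance for f in fragments)
    return True  # no testable payload: uninformative, never a conflict


# ---------------------------------------------------------------------------
# spectrum concordance
# ---------------------------------------------------------------------------


def _tolerant_jaccard(observed: list[float], theoretical: list[float], tol: float) -> float:
    """Jaccard-style overlap of two m/z lists under a matching tolerance."""
    if not observed or not theoretical:
        return 0.0
    obs = sorted(observed)
    theo = sorted(theoretical)
    i = j = matched = 0
    while i < len(obs) and j < len(theo):
        d = obs[i] - theo[j]
        if abs(d) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matched / (len(obs) + len(theo) - matched)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _equivalence_key(structure: GlycanStructure, mode: IonMode, cfg, panel):
    """Evidence-level identity of a candidate: its theoretical fragment m/z
    multiset plus its product labels under every panel reagent."""
    from .digestion import predict_product_labels

    frags = tuple(
        sorted(round(f.mz, 2) for f in enumerate_fragments(structure, mode, cfg.max_cuts))
    )
    digs = tuple(
        tuple(sorted(predict_product_labels(structure, panel[name])))
        for name in sorted(panel)
    )
    return frags, digs


def _merge_equivalent(
    annotations: list[Annotation], mode: IonMode, cfg, panel
) -> list[Annotation]:
    """Merge score-tied candidates that no panel experiment or fragment
    could distinguish; the lexicographically first form represents the
    class."""
    out: list[Annotation] = []
    i = 0
    while i < len(annotations):
        group = [annotations[i]]
        j = i + 1
        while (
            j < len(annotations)
            and abs(annotations[j].score - annotations[i].score) < 1e-9
        ):
            group.append(annotations[j])
            j += 1
        if len(group) == 1:
            out.append(group[0])
        else:
            by_key: dict = {}
            for ann in group:
                key = _equivalence_key(ann.structure, mode, cfg, panel)
                by_key.setdefault(key, []).append(ann)
            merged = []
            for anns in by_key.values():
                head = anns[0]
                head.equivalent.extend(a.structure for a in anns[1:])
                merged.append(head)
            merged.sort(
                key=lambda a: (
                    _unknown_linkages(a.structure),
                    a.structure.canonical(),
                )
            )
            out.extend(merged)
        i = j
    return out


def score_candidates(
    candidates: list[GlycanStructure],
    evidence: Optional[EvidenceSet],
    msms: Optional[PeakList],
    mode: IonMode,
    cfg: AnnotatorConfig,
    digestion_bonus: Optional[dict[str, float]] = None,
    panel: Optional[dict] = None,
) -> list[Annotation]:
    """Score and rank candidates; deterministic for identical inputs.

    score = sum(weights of supported assertions) - conflict penalties
            + digestion consistency bonus + bounded spectrum concordance.
    Score-tied candidates indistinguishable by any panel experiment are
    merged into one annotation; remaining ties are broken by fewer unknown
    linkages, then lexicographic serialization (stable, declared,
    arbitrary).
    """
    digestion_bonus = digestion_bonus or {}
    observed = sorted(p.mz for p in msms.peaks) if msms is not None else []
    annotations: list[Annotation] = []
    for s in candidates:
        frags = enumerate_fragments(s, mode, cfg.max_cuts)
        prec = precursor_mz(composition_of(s), mode)
        score = 0.0
        support: list[tuple[str, str]] = []
        if evidence is not None:
            for a in evidence.assertions:
                ok = candidate_supports(s, a, frags, prec, cfg.fragment_tolerance)
                if ok:
                    score += a.weight
                    support.append((a.motif, "supported"))
                else:
                    score -= cfg.conflict_penalty
                    support.append((a.motif, "conflict"))
        dig = digestion_bonus.get(s.canonical(), 0.0)
        score += dig
        spec_score = 0.0
        if observed:
            spec_score = cfg.spectrum_weight * _tolerant_jaccard(
                observed, [f.mz for f in frags], cfg.fragment_tolerance
            )
            score += spec_score
        annotations.append(Annotation(s, score, 0, support, dig, spec_score))
    annotations.sort(
        key=lambda a: (
            -a.score,
            _unknown_linkages(a.structure),
            a.structure.canonical(),
        )
    )
    if panel is not None:
        annotations = _merge_equivalent(annotations, mode, cfg, panel)
    for i, a in enumerate(annotations):
        a.rank = i + 1
    return annotations


def _unknown_linkages(s: GlycanStructure) -> int:
    n = 0
    for node in s.nodes():
        if node is s.root:
            continue
        if node.anomer is None:
            n += 1
        if node.position is None:
            n += 1
    return n


def _gu_bonus(comp: Composition, gu: float, cfg: AnnotatorConfig) -> float:
    if cfg.gu_increments is None:
        return 0.0
    predicted = cfg.gu_base + sum(
        cfg.gu_increments.get(k, 0.0) * v for k, v in comp.counts().items()
    )
    return cfg.gu_weight if abs(gu - predicted) <= cfg.gu_tolerance else 0.0


# ---------------------------------------------------------------------------
# the pipeline's top-level inference
# ---------------------------------------------------------------------------


def annotate(
    peaklist: PeakList,
    digests: Optional[list[DigestionObservation]] = None,
    gu: Optional[float] = None,
    grammar: Optional[MotifGrammar] = None,
    matcher_cfg: Optional[MatcherConfig] = None,
    classifier_cfg: Optional[ClassifierConfig] = None,
    cfg: Optional[AnnotatorConfig] = None,
    panel: Optional[dict[str, ReagentSpec]] = None,
    composition: Optional[Composition] = None,
) -> AnnotationResult:
    """Annotate one precursor: composition assignment, candidate
    enumeration, evidence extraction, digestion filtering, scoring.

    ``composition`` may pre-assign the precursor composition, otherwise the
    top-ranked match within tolerance is used (remaining candidates are
    reported). Candidates eliminated by a digestion observation are excluded
    and logged; an observation eliminating *every* candidate is flagged as a
    conflict and not applied.
    """
    from .model import n_glycan_grammar

    grammar = grammar or n_glycan_grammar()
    matcher_cfg = matcher_cfg or MatcherConfig()
    classifier_cfg = classifier_cfg or ClassifierConfig()
    cfg = cfg or AnnotatorConfig()
    panel = panel or default_panel()
    mode = matcher_cfg.mode

    comp_candidates: list[CompositionCandidate] = []
    if composition is None:
        if peaklist.precursor_mz is None:
            raise ValueError("peak list has no precursor m/z")
        comp_candidates = match_composition(peaklist.precursor_mz, matcher_cfg)
        if not comp_candidates:
            return AnnotationResult(
                None, [], [], "unresolved", reason="no composition within tolerance"
            )
        composition = comp_candidates[0].composition

    cand_set = enumerate_candidates(composition, grammar, cfg.enumeration_cap)
    result = AnnotationResult(
        composition, comp_candidates, [], "unresolved",
        truncated=cand_set.truncated, reason=cand_set.reason,
    )
    if not cand_set.structures:
        return result

    evidence: Optional[EvidenceSet] = None
    if peaklist.peaks:
        evidence = classify_spectrum(
            composition, peaklist, mode, classifier_cfg,
            precursor_mz_obs=peaklist.precursor_mz,
        )
    result.evidence = evidence

    candidates = list(cand_set.structures)
    digestion_bonus: dict[str, float] = {}
    for obs in digests or []:
        shift = interpret_shift(obs, candidates, panel, grammar=None)
        if shift.conflict:
            result.conflicts.append(
                f"{obs.reagent}: no candidate reproduces product {obs.product_label}"
            )
            continue
        surviving = {s.canonical() for s in shift.survivors}
        for s in candidates:
            if s.canonical() not in surviving:
                result.eliminated.append(
                    (s.canonical(), f"{obs.reagent} -> {obs.product_label}")
                )
        candidates = shift.survivors
        w = panel[obs.reagent].weight
        for s in candidates:
            digestion_bonus[s.canonical()] = digestion_bonus.get(s.canonical(), 0.0) + w

    if not candidates:
        result.tier = "unresolved"
        result.reason = "all candidates eliminated by digestion evidence"
        return result

    annotations = score_candidates(
        candidates, evidence, peaklist if peaklist.peaks else None, mode, cfg,
        digestion_bonus, panel,
    )
    if gu is not None:
        bonus = _gu_bonus(composition, gu, cfg)
        for a in annotations:
            a.score += bonus

    result.annotations = annotations
    if len(annotations) >= 2 and abs(annotations[0].score - annotations[1].score) < 1e-9:
        result.tier = "ambiguous"
    else:
        result.tier = "unique"
    return result
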