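"""Monosaccharide composition assignment and glycan-series detection.

Precursor masses are matched against the bounded composition lattice
(complete enumeration within the configured maxima); observed MALDI-TOF
deviations are typically 0.1-0.2 Da, so the default tolerance is 0.25 Da
with a safety margin. Isobaric ambiguity within tolerance is surfaced in
the ranked candidate list, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .masses import IonMode, POSITIVE, precursor_mz
from .model import Composition
from .spectra import PeakList

__all__ = [
    "MatcherConfig",
    "CompositionCandidate",
    "match_composition",
    "detect_series",
    "SeriesGroup",
    "SERIES_INCREMENTS",
]

#: mass increments recognized in glycan ladders (Da)
SERIES_INCREMENTS = {
    "Hex": 162.053,
    "HexNAc": 203.079,
    "Fuc": 146.058,
    "MeFuc": 160.074,
    "PC": 165.055,
    "Me": 14.016,
}


@dataclass(frozen=True)
class MatcherConfig:
    """Tolerance, count bounds, label state and ion mode for matching.

    N-glycan (PA) bounds exclude hexuronic acid (no anionic N-glycans were
    found); O-glycan (alditol) bounds admit HexA but no methylation.
    """

    tolerance: float = 0.25
    max_hex: int = 9
    max_hexnac: int = 8
    max_fuc: int = 5
    max_hexa: int = 0
    max_me: int = 2
    max_pc: int = 2
    label_state: str = "PA"
    mode: IonMode = POSITIVE

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def n_glycan(cls, **overrides) -> "MatcherConfig":
        return cls(**overrides)

    @classmethod
    def o_glycan(cls, **overrides) -> "MatcherConfig":
        from .masses import NEGATIVE

        defaults = dict(
            label_state="alditol", mode=NEGATIVE, max_hexa=2, max_me=0,
            max_hex=6, max_hexnac=6,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class CompositionCandidate:
    composition: Composition
    delta: float  # observed - theoretical (Da)
    rank: int
    feasible: bool = True  # admits at least one grammar-consistent structure


def _feasibility_grammar(cfg: MatcherConfig):
    from .model import n_glycan_grammar, o_glycan_grammar

    if cfg.label_state == "alditol":
        return o_glycan_grammar()
    return n_glycan_grammar()


def _is_feasible(comp: Composition, cfg: MatcherConfig) -> bool:
    """Does the motif grammar admit any structure with this composition?

    Near-isobaric lattice points (e.g. Hex6 vs HexNAc4Fuc1Me1, 74 mDa
    apart) are usually not interpretable as glycans at all; feasible
    compositions are ranked ahead of infeasible ones, which remain listed
    so that ambiguity is surfaced rather than silently resolved.
    """
    from .enumeration import enumerate_candidates

    return len(enumerate_candidates(comp, _feasibility_grammar(cfg), cap=1)) > 0


def match_composition(mz: float, cfg: MatcherConfig) -> list[CompositionCandidate]:
    """All compositions within bounds whose theoretical m/z is within
    tolerance of the observed value, ranked by |delta| then by fewer
    distinct residue classes (display order only; ties are real ambiguity).
    """
    base = precursor_mz(Composition(label_state=cfg.label_state), cfg.mode)
    if mz <= base - cfg.tolerance:
        return []
    hits: list[tuple[float, int, str, Composition]] = []
    # bounded lattice walk with mass pruning
    for h in range(cfg.max_hex + 1):
        m_h = base + h * 162.0528
        if m_h - cfg.tolerance > mz:
            break
        for n in range(cfg.max_hexnac + 1):
            m_n = m_h + n * 203.0794
            if m_n - cfg.tolerance > mz:
                break
            for f in range(cfg.max_fuc + 1):
                m_f = m_n + f * 146.0579
                if m_f - cfg.tolerance > mz:
                    break
                for a in range(cfg.max_hexa + 1):
                    m_a = m_f + a * 176.0321
                    if m_a - cfg.tolerance > mz:
                        break
                    for me in range(cfg.max_me + 1):
                        m_me = m_a + me * 14.0157
                        if m_me - cfg.tolerance > mz:
                            break
                        for pc in range(cfg.max_pc + 1):
                            theo = m_me + pc * 165.0555
                            if theo - cfg.tolerance > mz:
                                break
                            delta = mz - theo
                            if abs(delta) <= cfg.tolerance:
                                comp = Composition(h, n, f, a, me, pc, cfg.label_state)
                                classes = sum(
                                    1 for v in (h, n, f, a, me, pc) if v > 0
                                )
                                feasible = _is_feasible(comp, cfg)
                                hits.append(
                                    (not feasible, abs(delta), classes, str(comp), comp)
                                )
    # Observed deviations are typically up to 0.1 Da: candidates within the
    # same 0.1-Da deviation band are ranked by parsimony (fewer residue
    # classes) before the exact |delta|; grammar-feasible compositions come
    # first throughout.
    hits.sort(
        key=lambda t: (t[0], int(t[1] / 0.1), t[2], round(t[1], 9), t[3])
    )
    out = []
    for rank, (infeasible, _, _, _, comp) in enumerate(hits, start=1):
        theo = precursor_mz(comp, cfg.mode)
        out.append(CompositionCandidate(comp, mz - theo, rank, not infeasible))
    return out


@dataclass
class SeriesGroup:
    """A maximal chain of peaks related by residue-mass increments."""

    mzs: list[float]
    increments: list[str]  # one per step, len == len(mzs) - 1


def detect_series(peaks: PeakList, cfg: Optional[MatcherConfig] = None) -> list[SeriesGroup]:
    """Maximal ascending chains of peaks differing by a residue increment.

    Peaks are linked when their difference matches one of the recognized
    increments (Hex/HexNAc/Fuc/MeFuc/PC/Me) within tolerance; each edge is
    annotated with the closest increment. Returns chains of length >= 2.
    """
    cfg = cfg or MatcherConfig()
    mzs = sorted(set(round(p.mz, 6) for p in peaks))
    n = len(mzs)
    if n < 2:
        return []
    succ: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
    has_pred = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            diff = mzs[j] - mzs[i]
            if diff > max(SERIES_INCREMENTS.values()) + cfg.tolerance:
                break
            best = min(SERIES_INCREMENTS.items(), key=lambda kv: abs(diff - kv[1]))
            if abs(diff - best[1]) <= cfg.tolerance:
                succ[i].append((j, best[0]))
                has_pred[j] = True

    groups: list[SeriesGroup] = []
    MAX_CHAINS = 1000

    def extend(path: list[int], incs: list[str]) -> None:
        if len(groups) >= MAX_CHAINS:
            return
        last = path[-1]
        if not succ[last]:
            if len(path) >= 2:
                groups.append(SeriesGroup([mzs[k] for k in path], list(incs)))
            return
        for j, name in succ[last]:
            extend(path + [j], incs + [name])

    for i in range(n):
        if not has_pred[i]:
            extend([i], [])
    return groups
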