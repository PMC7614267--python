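"""Monoisotopic masses, m/z labels, and B/Y/Z fragment enumeration.

Singly charged ions only: pyridylaminated N-glycans are measured as [M+H]+
(MALDI-TOF), reduced O-glycans as [M-H]- (LC-ESI). Fragment nomenclature
follows Domon-Costello: B/C ions retain the nonreducing side of a cleaved
glycosidic bond, Y/Z the reducing (labelled) side; B is the oxocarbenium
(residue sum plus proton in positive mode). Cross-ring (A/X) fragments are
not generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from .model import Composition, GlycanStructure, Node

__all__ = [
    "RESIDUE_MASS",
    "SUBSTITUENT_MASS",
    "LABEL_MASS",
    "WATER",
    "PROTON",
    "TRIMETHYLAMINE",
    "CO2",
    "IonMode",
    "POSITIVE",
    "NEGATIVE",
    "Fragment",
    "neutral_mass",
    "precursor_mz",
    "mz_label",
    "enumerate_fragments",
    "complementarity_check",
    "fragment_table",
]

#: residue monoisotopic masses (Da); Hex covers Man/Gal/Glc, HexNAc covers
#: GlcNAc/GalNAc -- MS cannot distinguish the epimers.
RESIDUE_MASS = {
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "Fuc": 146.0579,
    "HexA": 176.0321,
}

SUBSTITUENT_MASS = {"Me": 14.0157, "PC": 165.0555}

#: reducing-end label deltas: 2-aminopyridine adds 78.0582 Da, reduction to
#: the alditol adds 2.0157 Da (2 H).
LABEL_MASS = {"PA": 78.0582, "alditol": 2.0157, "free": 0.0}

WATER = 18.0106
PROTON = 1.00728
TRIMETHYLAMINE = 59.0735  # N(CH3)3, diagnostic loss from phosphorylcholine
CO2 = 43.9898


@dataclass(frozen=True)
class IonMode:
    """Ionization polarity; one adduct per spectrum, single charge only."""

    polarity: str  # "positive" ([M+H]+) or "negative" ([M-H]-)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def sign(self) -> int:
        return 1 if self.polarity == "positive" else -1

    def ionize(self, neutral: float) -> float:
        return neutral + self.sign * PROTON


POSITIVE = IonMode("positive")
NEGATIVE = IonMode("negative")


def neutral_mass(c: Composition) -> float:
    """Monoisotopic neutral mass: residue sum + substituents + water + label."""
    m = (
        c.hex * RESIDUE_MASS["Hex"]
        + c.hexnac * RESIDUE_MASS["HexNAc"]
        + c.fuc * RESIDUE_MASS["Fuc"]
        + c.hexa * RESIDUE_MASS["HexA"]
        + c.me * SUBSTITUENT_MASS["Me"]
        + c.pc * SUBSTITUENT_MASS["PC"]
    )
    return m + WATER + LABEL_MASS[c.label_state]


def precursor_mz(c: Composition, mode: IonMode) -> float:
    return mode.ionize(neutral_mass(c))


def mz_label(mz: float) -> int:
    """Integer m/z label by truncation of the monoisotopic m/z.

    Printed glycan labels truncate rather than round (1637.60 -> 1637,
    2235.85 -> 2235). A 1e-9 guard absorbs float representation noise.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return math.floor(mz + 1e-9)


@dataclass(frozen=True)
class Fragment:
    """A glycosidic fragment ion.

    ``kind`` is B, Y, Z, internal (double-cut), or precursor (for
    precursor-derived neutral-loss variants); ``losses`` names applied
    neutral losses; ``cut_edges`` are preorder edge indices (provenance).
    """

    kind: str
    mz: float
    composition: Composition
    cut_edges: tuple[int, ...] = ()
    losses: tuple[str, ...] = ()

    @property
    def label(self) -> int:
        return mz_label(self.mz)


def _residue_sum(node: Node) -> float:
    m = RESIDUE_MASS[node.residue] + sum(SUBSTITUENT_MASS[s] for s in node.substituents)
    return m + sum(_residue_sum(c) for c in node.children)


def _subtree_comp(node: Node) -> Composition:
    counts = {"Hex": 0, "HexNAc": 0, "Fuc": 0, "HexA": 0, "Me": 0, "PC": 0}
    stack = [node]
    while stack:
        n = stack.pop()
        counts[n.residue] += 1
        for s in n.substituents:
            counts[s] += 1
        stack.extend(n.children)
    return Composition(
        counts["Hex"], counts["HexNAc"], counts["Fuc"], counts["HexA"],
        counts["Me"], counts["PC"], "free",
    )


def _retained_has_subterminal_hexa(structure: GlycanStructure, removed: set[int]) -> bool:
    """True if a HexA that is subterminal in the parent structure survives
    in the retained (reducing-side) part; carboxyl loss is characteristic of
    Z/Y ions retaining such residues."""
    for n in structure.nodes():
        if id(n) in removed:
            continue
        if n.residue == "HexA" and n.children:
            return True
    return False


def enumerate_fragments(
    s: GlycanStructure, mode: IonMode, max_cuts: int = 2
) -> list[Fragment]:
    """Exhaustive single- (and optionally double-) cut glycosidic fragments.

    One B and one Y (plus Z in negative mode) per cut edge; double cuts give
    internal fragments (nested cuts, B-type) and doubly truncated Y ions
    (disjoint cuts). Negative-mode extras: a -59.0735 trimethylamine-loss
    variant for every PC-containing fragment and for the precursor, and a
    -43.9898 CO2-loss variant for Y/Z ions retaining a subterminal
    hexuronic acid. Deduplicated by (kind, m/z).
    """
    if max_cuts not in (1, 2):
        raise ValueError("max_cuts must be 1 or 2")
    edges = s.edges()
    total = _residue_sum(s.root)
    label = LABEL_MASS[s.label_state]
    sub_mass = [_residue_sum(child) for _, child in edges]
    sub_comp = [_subtree_comp(child) for _, child in edges]
    sub_ids = [
        {id(n) for n in GlycanStructure(child, "free").nodes()} for _, child in edges
    ]
    total_comp = _subtree_comp(s.root)
    sign = mode.sign
    neg = mode.polarity == "negative"

    frags: dict[tuple[str, float], Fragment] = {}

    def emit(kind, mass, comp, cuts, losses=()):
        mz = mass + sign * PROTON
        if mz <= 0:
            return
        key = (kind, round(mz, 4))
        if key not in frags:
            frags[key] = Fragment(kind, mz, comp, cuts, losses)

    def with_variants(kind, mass, comp, cuts, removed_ids):
        emit(kind, mass, comp, cuts)
        if neg and comp.pc > 0:
            emit(kind, mass - TRIMETHYLAMINE, comp, cuts, ("trimethylamine",))
        if (
            neg
            and kind in ("Y", "Z")
            and _retained_has_subterminal_hexa(s, removed_ids)
        ):
            emit(kind, mass - CO2, comp, cuts, ("CO2",))
            if comp.pc > 0:
                emit(kind, mass - CO2 - TRIMETHYLAMINE, comp, cuts, ("CO2", "trimethylamine"))

    for i in range(len(edges)):
        b_comp = sub_comp[i]
        with_variants("B", sub_mass[i], b_comp, (i,), set())
        y_mass = total - sub_mass[i] + WATER + label
        y_comp = Composition(
            total_comp.hex - b_comp.hex,
            total_comp.hexnac - b_comp.hexnac,
            total_comp.fuc - b_comp.fuc,
            total_comp.hexa - b_comp.hexa,
            total_comp.me - b_comp.me,
            total_comp.pc - b_comp.pc,
            s.label_state,
        )
        with_variants("Y", y_mass, y_comp, (i,), sub_ids[i])
        if neg:
            with_variants("Z", y_mass - WATER, y_comp, (i,), sub_ids[i])

    if max_cuts == 2:
        for i in range(len(edges)):
            for j in range(i + 1, len(edges)):
                if id(edges[j][1]) in sub_ids[i] or id(edges[i][1]) in sub_ids[j]:
                    # nested cuts: internal fragment, ionized B-like
                    outer, inner = (i, j) if id(edges[j][1]) in sub_ids[i] else (j, i)
                    mass = sub_mass[outer] - sub_mass[inner]
                    comp = sub_comp[outer].minus(sub_comp[inner])
                    with_variants("internal", mass, comp, (outer, inner), set())
                else:
                    # disjoint cuts: doubly truncated Y ion
                    mass = total - sub_mass[i] - sub_mass[j] + WATER + label
                    ci, cj = sub_comp[i], sub_comp[j]
                    comp = Composition(
                        total_comp.hex - ci.hex - cj.hex,
                        total_comp.hexnac - ci.hexnac - cj.hexnac,
                        total_comp.fuc - ci.fuc - cj.fuc,
                        total_comp.hexa - ci.hexa - cj.hexa,
                        total_comp.me - ci.me - cj.me,
                        total_comp.pc - ci.pc - cj.pc,
                        s.label_state,
                    )
                    with_variants("Y", mass, comp, (i, j), sub_ids[i] | sub_ids[j])

    # precursor trimethylamine loss: the negative-mode PC diagnostic
    if neg and total_comp.pc > 0:
        prec = total + WATER + label
        emit(
            "precursor",
            prec - TRIMETHYLAMINE,
            Composition(
                total_comp.hex, total_comp.hexnac, total_comp.fuc,
                total_comp.hexa, total_comp.me, total_comp.pc, s.label_state,
            ),
            (),
            ("trimethylamine",),
        )

    out = list(frags.values())
    out.sort(key=lambda f: (f.mz, f.kind))
    return out


def complementarity_check(b: Fragment, y: Fragment, precursor: float) -> bool:
    """QC identity for a complementary single-cut B/Y pair (positive mode):
    B + Y must reconstruct the protonated precursor plus one proton."""
    if b.kind != "B" or y.kind != "Y":
        raise ValueError("expects a B and a Y fragment")
    if b.losses or y.losses or len(b.cut_edges) != 1 or len(y.cut_edges) != 1:
        raise ValueError("expects plain single-cut fragments")
    if b.cut_edges != y.cut_edges:
        return False
    return abs(b.mz + y.mz - (precursor + PROTON)) < 0.01


def fragment_table(fragments: list[Fragment]) -> "pandas.DataFrame":  # noqa: F821
    """Fragment list as a DataFrame (exportable as delimited text)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "type": [f.kind for f in fragments],
            "label": [f.label for f in fragments],
            "mz": [round(f.mz, 4) for f in fragments],
            "composition": [str(f.composition) for f in fragments],
            "losses": ["+".join(f.losses) for f in fragments],
            "cut_edges": [";".join(map(str, f.cut_edges)) for f in fragments],
        }
    )
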