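"""Exoglycosidase / chemical digestion reasoning.

Reagent specificities are combinations of primitives (e.g. "remove terminal
alpha-galactose", "remove alpha-1,3-linked core fucose together with its
substituents") applied to candidate trees to exhaustion. Observed
before/after mass shifts then filter candidate structures: a candidate
survives when its predicted product set reproduces the observed product
label. Reagents with incomplete conversion (PCE, HF on the bisect fucose,
chitinase) admit every intermediate as an observable product; removals that
depend on unresolved epimer identity (HEX-4 on an unknown terminal HexNAc)
are admissible rather than mandatory, so unknown identity never falsely
eliminates a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

import yaml

from .masses import POSITIVE, NEGATIVE, IonMode, mz_label, precursor_mz
from .model import GlycanStructure, Node, composition_of

__all__ = [
    "ReagentSpec",
    "DigestionObservation",
    "ShiftResult",
    "load_reagent_panel",
    "default_panel",
    "predict_products",
    "predict_product_labels",
    "interpret_shift",
    "RECOVERY_PANEL",
]

#: default three-reagent panel for synthetic recovery experiments: HF for
#: the alpha-1,3/alpha-1,2-fucose and PC chemistry, the linkage-restricted
#: alpha-mannosidase that separates mannose-arm topologies, and the broad
#: alpha-mannosidase that separates galactose from mannose placements.
RECOVERY_PANEL = ("hf", "a23-man", "jackbean-man")


@dataclass(frozen=True)
class ReagentSpec:
    name: str
    display: str
    primitives: tuple[str, ...]
    partial: bool = False
    weight: float = 2.0


@dataclass(frozen=True)
class DigestionObservation:
    """A before/after digestion measurement on one precursor."""

    parent_label: int
    reagent: str
    product_label: int  # equals parent_label when unchanged

    def __post_init__(self) -> None:
        if self.product_label > self.parent_label:
            raise ValueError("removal reagents cannot increase the mass")


# ---------------------------------------------------------------------------
# removal primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Removal:
    """One applicable excision: a node path (subtree removal) or a PC/Me
    substituent strip; ``optional`` marks admissible-but-not-mandatory
    removals (partial chemistry or unknown epimer identity)."""

    path: tuple[int, ...]
    kind: str  # "subtree" | "pc"
    optional: bool = False


def _iter_nodes(structure: GlycanStructure):
    """Yield (node, parent, path) preorder."""
    stack: list[tuple[Node, Optional[Node], tuple[int, ...]]] = [(structure.root, None, ())]
    while stack:
        node, parent, path = stack.pop()
        yield node, parent, path
        for i in reversed(range(len(node.children))):
            stack.append((node.children[i], node, path + (i,)))


def _is_terminal(node: Node) -> bool:
    return not node.children and not node.substituents


def _chain_has_pc(structure: GlycanStructure, path: tuple[int, ...]) -> bool:
    """Any PC on the maximal HexNAc chain containing the node at ``path``."""
    # walk down from root along path, remember the last non-HexNAc ancestor
    node = structure.root
    chain_start = 0
    nodes_on_path = [node]
    for step in path:
        node = node.children[step]
        nodes_on_path.append(node)
    for i, n in enumerate(nodes_on_path):
        if n.residue != "HexNAc":
            chain_start = i + 1
    chain = nodes_on_path[chain_start:]
    return any("PC" in n.substituents for n in chain)


def _prim_bisect_a2_fucosidase(structure, grammar_unused=None):
    """Fuc-alpha-1,2 on the bisecting galactose; blocked when methylated."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Fuc"
            and node.anomer != "b"
            and node.position == 2
            and parent is not None
            and parent.residue == "Hex"
            and parent.anomer == "b"
            and "Me" not in node.substituents
            and not node.children
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_alpha_galactosidase(structure, grammar_unused=None):
    """Terminal alpha-galactose (on core alpha-1,3-fucose or on mannose)."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Hex"
            and node.identity in ("Gal",)
            and node.anomer == "a"
            and _is_terminal(node)
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_corefuc_beta_galactosidase(structure, grammar_unused=None):
    """Terminal beta-galactose of the chain on the core alpha-1,6-fucose."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if not (
            node.residue == "Hex"
            and node.identity in (None, "Gal")
            and node.anomer != "a"
            and _is_terminal(node)
            and parent is not None
        ):
            continue
        # parent chain must bottom out in a Fuc alpha-1,6 on the root
        anc = structure.root
        chain = [anc]
        for step in path:
            anc = anc.children[step]
            chain.append(anc)
        # chain[-1] is the Gal; walk back over Hex until the fucose
        i = len(chain) - 2
        while i >= 0 and chain[i].residue == "Hex":
            i -= 1
        if i >= 1 and chain[i].residue == "Fuc" and chain[i].position == 6 and i == 1:
            out.append(Removal(path, "subtree"))
    return out


def _prim_bisect_beta_galactosidase(structure, grammar_unused=None):
    """Terminal bisecting beta-Gal on the beta-mannose; sterically blocked
    when the distal GlcNAc is substituted (fucosylated)."""
    root = structure.root
    distal = next((c for c in root.children if c.residue == "HexNAc"), None)
    if distal is None:
        return []
    if any(c.residue == "Fuc" for c in distal.children):
        return []  # steric hindrance by the modified distal GlcNAc
    beta = next((c for c in distal.children if c.residue == "Hex"), None)
    if beta is None:
        return []
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            parent is beta
            and node.residue == "Hex"
            and node.anomer == "b"
            and node.position == 4
            and node.identity in (None, "Gal")
            and _is_terminal(node)
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_galnac_hexosaminidase(structure, grammar_unused=None):
    """HEX-4: terminal beta-GalNAc (LacdiNAc terminus). Unknown identity or
    a PC-containing chain context makes removal admissible, not mandatory."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if not (
            node.residue == "HexNAc"
            and _is_terminal(node)
            and parent is not None
            and node.anomer != "a"
        ):
            continue
        if node.identity == "GlcNAc":
            continue
        optional = node.identity is None or _chain_has_pc(structure, path)
        out.append(Removal(path, "subtree", optional=optional))
    return out


def _prim_broad_hexosaminidase(structure, grammar_unused=None):
    """Jack bean: any terminal HexNAc, except within PC-modified chains."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "HexNAc"
            and _is_terminal(node)
            and parent is not None
            and not _chain_has_pc(structure, path)
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_chito_chain_hexosaminidase(structure, grammar_unused=None):
    """Chitinase (conservative): terminal GlcNAc of a PC-free HexNAc chain
    of length >= 2; admissible only (the panel uses it citationally)."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "HexNAc"
            and node.identity in (None, "GlcNAc")
            and _is_terminal(node)
            and parent is not None
            and parent.residue == "HexNAc"
            and not _chain_has_pc(structure, path)
        ):
            out.append(Removal(path, "subtree", optional=True))
    return out


def _prim_broad_alpha_mannosidase(structure, grammar_unused=None):
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Hex"
            and node.identity in (None, "Man")
            and node.anomer == "a"
            and _is_terminal(node)
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_a23_alpha_mannosidase(structure, grammar_unused=None):
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Hex"
            and node.identity in (None, "Man")
            and node.anomer == "a"
            and node.position in (2, 3)
            and _is_terminal(node)
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_pc_esterase(structure, grammar_unused=None):
    out = []
    for node, parent, path in _iter_nodes(structure):
        if "PC" in node.substituents:
            out.append(Removal(path, "pc"))
    return out


def _prim_hf_a3_fucose(structure, grammar_unused=None):
    """HF removes alpha-1,3-fucose (proximal and distal) together with any
    residues attached to it; complete."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Fuc"
            and node.anomer != "b"
            and node.position == 3
            and parent is not None
            and parent.residue == "HexNAc"
        ):
            out.append(Removal(path, "subtree"))
    return out


def _prim_hf_pc(structure, grammar_unused=None):
    return [
        Removal(path, "pc")
        for node, _, path in _iter_nodes(structure)
        if "PC" in node.substituents
    ]


def _prim_hf_bisect_fucose(structure, grammar_unused=None):
    """HF removes the (methyl)fucose on the bisecting galactose, partially."""
    out = []
    for node, parent, path in _iter_nodes(structure):
        if (
            node.residue == "Fuc"
            and node.anomer != "b"
            and node.position == 2
            and parent is not None
            and parent.residue == "Hex"
        ):
            out.append(Removal(path, "subtree", optional=True))
    return out


_PRIMITIVES: dict[str, Callable] = {
    "bisect_a2_fucosidase": _prim_bisect_a2_fucosidase,
    "alpha_galactosidase": _prim_alpha_galactosidase,
    "corefuc_beta_galactosidase": _prim_corefuc_beta_galactosidase,
    "bisect_beta_galactosidase": _prim_bisect_beta_galactosidase,
    "galnac_hexosaminidase": _prim_galnac_hexosaminidase,
    "broad_hexosaminidase": _prim_broad_hexosaminidase,
    "chito_chain_hexosaminidase": _prim_chito_chain_hexosaminidase,
    "broad_alpha_mannosidase": _prim_broad_alpha_mannosidase,
    "a23_alpha_mannosidase": _prim_a23_alpha_mannosidase,
    "pc_esterase": _prim_pc_esterase,
    "hf_a3_fucose": _prim_hf_a3_fucose,
    "hf_pc": _prim_hf_pc,
    "hf_bisect_fucose": _prim_hf_bisect_fucose,
}


# ---------------------------------------------------------------------------
# panel loading
# ---------------------------------------------------------------------------


def load_reagent_panel(path=None) -> dict[str, ReagentSpec]:
    """Load the reagent panel from YAML (the packaged default if no path)."""
    if path is None:
        text = resources.files("glycanpipe.data").joinpath("reagent_panel.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    panel: dict[str, ReagentSpec] = {}
    for entry in doc["reagents"]:
        prims = tuple(entry["primitives"])
        for p in prims:
            if p not in _PRIMITIVES:
                raise ValueError(f"unknown specificity primitive {p!r}")
        panel[entry["name"]] = ReagentSpec(
            entry["name"],
            entry.get("display", entry["name"]),
            prims,
            bool(entry.get("partial", False)),
            float(entry.get("weight", 2.0)),
        )
    return panel


_DEFAULT_PANEL: Optional[dict[str, ReagentSpec]] = None


def default_panel() -> dict[str, ReagentSpec]:
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        _DEFAULT_PANEL = load_reagent_panel()
    return _DEFAULT_PANEL


# ---------------------------------------------------------------------------
# product prediction
# ---------------------------------------------------------------------------


def _apply_removal(structure: GlycanStructure, removal: Removal) -> GlycanStructure:
    out = structure.copy()
    node = out.root
    parent = None
    for step in removal.path:
        parent = node
        node = node.children[step]
    if removal.kind == "subtree":
        if parent is None:
            raise ValueError("cannot remove the reducing-end residue")
        parent.children.remove(node)
    elif removal.kind == "pc":
        subs = list(node.substituents)
        subs.remove("PC")
        node.substituents = tuple(subs)
    else:
        raise ValueError(f"unknown removal kind {removal.kind!r}")
    return out


def _mode_for(structure: GlycanStructure) -> IonMode:
    return NEGATIVE if structure.label_state == "alditol" else POSITIVE


def structure_label(structure: GlycanStructure, mode: Optional[IonMode] = None) -> int:
    """Integer precursor label of a structure in its native ion mode."""
    mode = mode or _mode_for(structure)
    return mz_label(precursor_mz(composition_of(structure), mode))


def predict_products(
    s: GlycanStructure, r: ReagentSpec, max_states: int = 512
) -> list[tuple[GlycanStructure, int]]:
    """Digestion products of ``s`` under reagent ``r`` as (structure, label).

    All removable targets are excised iteratively. For partial reagents
    every reachable intermediate (including the unchanged parent) is a
    product; otherwise only states with no mandatory removal left. Products
    are unique by canonical form, sorted by descending label then form.
    """
    mode = _mode_for(s)
    seen: dict[str, GlycanStructure] = {}
    products: dict[str, GlycanStructure] = {}
    frontier = [s.copy()]
    while frontier:
        st = frontier.pop()
        key = st.canonical()
        if key in seen:
            continue
        if len(seen) >= max_states:
            break
        seen[key] = st
        removals: list[Removal] = []
        for prim in r.primitives:
            removals.extend(_PRIMITIVES[prim](st))
        mandatory = [x for x in removals if not x.optional]
        if r.partial or not mandatory:
            products[key] = st
        for removal in removals:
            frontier.append(_apply_removal(st, removal))
    out = [(st, structure_label(st, mode)) for st in products.values()]
    out.sort(key=lambda t: (-t[1], t[0].canonical()))
    return out


def predict_product_labels(s: GlycanStructure, r: ReagentSpec) -> set[int]:
    return {label for _, label in predict_products(s, r)}


# ---------------------------------------------------------------------------
# shift interpretation
# ---------------------------------------------------------------------------


@dataclass
class ShiftResult:
    """Outcome of filtering candidates against one digestion observation."""

    survivors: list[GlycanStructure]
    assertions: list[str] = field(default_factory=list)
    conflict: bool = False  # empty survivor set: evidence inconsistency


def interpret_shift(
    obs: DigestionObservation,
    candidates: list[GlycanStructure],
    panel: Optional[dict[str, ReagentSpec]] = None,
    grammar=None,
) -> ShiftResult:
    """Retain candidates whose predicted products reproduce the observation.

    Emits the motif names shared by every survivor when a grammar is given.
    An empty survivor set is flagged as an evidence conflict rather than
    failing silently.
    """
    panel = panel or default_panel()
    if obs.reagent not in panel:
        raise KeyError(f"unknown reagent {obs.reagent!r}")
    reagent = panel[obs.reagent]
    survivors = [
        c for c in candidates if obs.product_label in predict_product_labels(c, reagent)
    ]
    result = ShiftResult(survivors)
    if not survivors:
        result.conflict = True
        return result
    if grammar is not None:
        from .model import match_motifs

        common: Optional[set[str]] = None
        for c in survivors:
            names = {name for name, _ in match_motifs(c, grammar)}
            common = names if common is None else common & names
        result.assertions = sorted(common or ())
    return result
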