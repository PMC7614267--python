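"""Domain model for nematode glycan structures.

Glycans are rooted trees of monosaccharide residues. MS cannot distinguish
epimers, so residues are grouped into mass classes (Hex covers Man/Gal/Glc,
HexNAc covers GlcNAc/GalNAc); each node may additionally carry an *identity*
tag (e.g. ``Man`` vs ``Gal``) that is metadata used only by reagent
specificity rules, never by the mass engine.

The module also defines the motif grammar that bounds the candidate
structure space for *C. elegans* N-glycans (chitobiose core with up to three
core fucoses, galactosylated core fucoses, bisecting galactose with optional
(methyl)fucose, alpha-galactosylated mannose, and HexNAc-based antennae
optionally substituted with phosphorylcholine) and a reduced mucin-type
O-glycan grammar (core-1 based, with hexuronic acid and phosphorylcholine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "RESIDUE_CLASSES",
    "IDENTITY_CLASS",
    "LABEL_STATES",
    "Node",
    "GlycanStructure",
    "Composition",
    "MotifGrammar",
    "StructureError",
    "GrammarError",
    "composition_of",
    "match_motifs",
    "validate_structure",
    "parse_structure",
    "n_glycan_grammar",
    "o_glycan_grammar",
]

RESIDUE_CLASSES = ("Hex", "HexNAc", "Fuc", "HexA")

#: identity tag -> mass class
IDENTITY_CLASS = {
    "Man": "Hex",
    "Gal": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Fuc": "Fuc",
    "GlcA": "HexA",
}

SUBSTITUENTS = ("Me", "PC")

LABEL_STATES = ("PA", "alditol", "free")
_LABEL_TOKEN = {"PA": "PA", "alditol": "ol", "free": "free"}
_TOKEN_LABEL = {v: k for k, v in _LABEL_TOKEN.items()}


class StructureError(ValueError):
    """Malformed glycan tree (cycle, orphan node, bad field values)."""


class GrammarError(ValueError):
    """Structure violates the motif grammar."""


@dataclass
class Node:
    """One monosaccharide residue in a glycan tree.

    ``anomer`` is ``'a'``/``'b'``/``None`` (unknown) and ``position`` is the
    attachment position on the parent (1-6) or ``None``; linkage knowledge is
    tri-state and evidence may only upgrade unknown to known.
    """

    residue: str
    identity: Optional[str] = None
    substituents: tuple[str, ...] = ()
    anomer: Optional[str] = None
    position: Optional[int] = None
    children: list["Node"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residue not in RESIDUE_CLASSES:
            raise StructureError(f"unknown residue class {self.residue!r}")
        if self.identity is not None and IDENTITY_CLASS.get(self.identity) != self.residue:
            raise StructureError(
                f"identity {self.identity!r} inconsistent with class {self.residue!r}"
            )
        for s in self.substituents:
            if s not in SUBSTITUENTS:
                raise StructureError(f"unknown substituent {s!r}")

    def add(self, child: "Node") -> "Node":
        self.children.append(child)
        return child

    def copy(self) -> "Node":
        return Node(
            self.residue,
            self.identity,
            tuple(self.substituents),
            self.anomer,
            self.position,
            [c.copy() for c in self.children],
        )

    def serialize(self, with_identity: bool = True, _root: bool = True) -> str:
        name = self.identity if (with_identity and self.identity) else self.residue
        subs = "".join("+" + s for s in sorted(self.substituents))
        link = ""
        if not _root:
            link = "@%s%s" % (self.anomer or "?", self.position if self.position else "?")
        kids = ""
        if self.children:
            parts = sorted(c.serialize(with_identity, _root=False) for c in self.children)
            kids = "(" + ",".join(parts) + ")"
        return name + subs + link + kids


@dataclass
class GlycanStructure:
    """Rooted glycan tree; the root is the reducing-end residue and carries
    the label state (pyridylaminated, reduced alditol, or free)."""

    root: Node
    label_state: str = "free"

    def __post_init__(self) -> None:
        if self.label_state not in LABEL_STATES:
            raise StructureError(f"unknown label state {self.label_state!r}")

    # -- traversal -------------------------------------------------------
    def nodes(self) -> list[Node]:
        """Preorder node list; raises StructureError on a cyclic 'tree'."""
        out: list[Node] = []
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if id(n) in seen:
                raise StructureError("cycle detected in glycan tree")
            seen.add(id(n))
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def edges(self) -> list[tuple[Node, Node]]:
        """Preorder list of (parent, child) glycosidic edges."""
        out = []
        for n in self.nodes():
            for c in n.children:
                out.append((n, c))
        return out

    def copy(self) -> "GlycanStructure":
        return GlycanStructure(self.root.copy(), self.label_state)

    # -- serialization ---------------------------------------------------
    def serialize(self, with_identity: bool = True) -> str:
        return "%s:%s" % (_LABEL_TOKEN[self.label_state], self.root.serialize(with_identity))

    def canonical(self) -> str:
        """Serialization with sorted children: an equality key for trees."""
        return self.serialize(with_identity=True)

    def mass_canonical(self) -> str:
        """Canonical form with epimer identity tags stripped (what MS sees)."""
        return self.serialize(with_identity=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

_COMP_ORDER = ("Hex", "HexNAc", "Fuc", "HexA", "Me", "PC")


@dataclass(frozen=True)
class Composition:
    """Counts per residue class and substituent, plus reducing-end state."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    hexa: int = 0
    me: int = 0
    pc: int = 0
    label_state: str = "free"

    def __post_init__(self) -> None:
        for k in ("hex", "hexnac", "fuc", "hexa", "me", "pc"):
            if getattr(self, k) < 0:
                raise ValueError(f"negative count for {k}")
        if self.label_state not in LABEL_STATES:
            raise ValueError(f"unknown label state {self.label_state!r}")

    def counts(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "Fuc": self.fuc,
            "HexA": self.hexa,
            "Me": self.me,
            "PC": self.pc,
        }

    @property
    def n_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.hexa

    def __str__(self) -> str:
        c = self.counts()
        return "".join(f"{k}{c[k]}" for k in _COMP_ORDER if c[k]) or "empty"

    @classmethod
    def from_string(cls, text: str, label_state: str = "free") -> "Composition":
        """Parse a composition string such as ``Hex3HexNAc2Fuc1PC1``."""
        import re

        counts = dict.fromkeys(_COMP_ORDER, 0)
        pos = 0
        # longest names first so HexNAc/HexA are not eaten by Hex
        pat = re.compile(r"(HexNAc|HexA|Hex|Fuc|Me|PC)(\d+)")
        for m in pat.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition {text!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse composition {text!r}")
        return cls(
            hex=counts["Hex"],
            hexnac=counts["HexNAc"],
            fuc=counts["Fuc"],
            hexa=counts["HexA"],
            me=counts["Me"],
            pc=counts["PC"],
            label_state=label_state,
        )

    def minus(self, other: "Composition") -> "Composition":
        return Composition(
            self.hex - other.hex,
            self.hexnac - other.hexnac,
            self.fuc - other.fuc,
            self.hexa - other.hexa,
            self.me - other.me,
            self.pc - other.pc,
            self.label_state,
        )


def composition_of(structure: GlycanStructure) -> Composition:
    """Tally residue classes and substituents over a validated tree.

    The label state is propagated from the structure's reducing end.
    """
    counts = {"Hex": 0, "HexNAc": 0, "Fuc": 0, "HexA": 0, "Me": 0, "PC": 0}
    for n in structure.nodes():  # raises StructureError on cycles
        counts[n.residue] += 1
        for s in n.substituents:
            counts[s] += 1
    return Composition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        fuc=counts["Fuc"],
        hexa=counts["HexA"],
        me=counts["Me"],
        pc=counts["PC"],
        label_state=structure.label_state,
    )


# ---------------------------------------------------------------------------
# structure text-format parser
# ---------------------------------------------------------------------------


def _parse_node(text: str, pos: int, root: bool) -> tuple[Node, int]:
    import re

    m = re.compile(r"[A-Za-z]+").match(text, pos)
    if not m:
        raise ValueError(f"expected residue name at position {pos} in {text!r}")
    name = m.group(0)
    pos = m.end()
    if name in IDENTITY_CLASS:
        residue, identity = IDENTITY_CLASS[name], name
    elif name in RESIDUE_CLASSES:
        residue, identity = name, None
    else:
        raise ValueError(f"unknown residue token {name!r}")
    subs: list[str] = []
    while pos < len(text) and text[pos] == "+":
        m = re.compile(r"\+(Me|PC)").match(text, pos)
        if not m:
            raise ValueError(f"bad substituent at position {pos} in {text!r}")
        subs.append(m.group(1))
        pos = m.end()
    anomer: Optional[str] = None
    position: Optional[int] = None
    if pos < len(text) and text[pos] == "@":
        if root:
            raise ValueError("root residue must not carry a linkage")
        m = re.compile(r"@([ab?])([1-6?])").match(text, pos)
        if not m:
            raise ValueError(f"bad linkage at position {pos} in {text!r}")
        anomer = None if m.group(1) == "?" else m.group(1)
        position = None if m.group(2) == "?" else int(m.group(2))
        pos = m.end()
    elif not root:
        raise ValueError(f"non-root residue missing '@' linkage at position {pos}")
    node = Node(residue, identity, tuple(subs), anomer, position)
    if pos < len(text) and text[pos] == "(":
        pos += 1
        while True:
            child, pos = _parse_node(text, pos, root=False)
            node.children.append(child)
            if pos >= len(text):
                raise ValueError("unterminated child list")
            if text[pos] == ",":
                pos += 1
                continue
            if text[pos] == ")":
                pos += 1
                break
            raise ValueError(f"unexpected character {text[pos]!r} at position {pos}")
    return node, pos


def parse_structure(text: str) -> GlycanStructure:
    """Parse the condensed text encoding, inverse of ``serialize``."""
    if ":" not in text:
        raise ValueError("structure string must start with a label prefix (PA:/ol:/free:)")
    token, rest = text.split(":", 1)
    if token not in _TOKEN_LABEL:
        raise ValueError(f"unknown label token {token!r}")
    node, pos = _parse_node(rest, 0, root=True)
    if pos != len(rest):
        raise ValueError(f"trailing characters at position {pos} in {rest!r}")
    return GlycanStructure(node, _TOKEN_LABEL[token])


# ---------------------------------------------------------------------------
# motif grammar
# ---------------------------------------------------------------------------

#: mannose scaffold of the canonical Man9 N-glycan, keyed by arm path.
#: values: (parent key or None, anomer, position)
MAN_SCAFFOLD: dict[str, tuple[Optional[str], str, int]] = {
    "bMan": (None, "b", 4),
    "a3": ("bMan", "a", 3),
    "a3.2": ("a3", "a", 2),
    "a3.22": ("a3.2", "a", 2),
    "a6": ("bMan", "a", 6),
    "a63": ("a6", "a", 3),
    "a63.2": ("a63", "a", 2),
    "a66": ("a6", "a", 6),
    "a66.2": ("a66", "a", 2),
}

MAN5_KEYS = frozenset({"bMan", "a3", "a6", "a63", "a66"})
ALPHA2_KEYS = frozenset({"a3.2", "a3.22", "a63.2", "a66.2"})


def mannose_scaffolds(max_man: int = 9) -> list[frozenset[str]]:
    """All grammar-admissible mannose scaffolds (connected subsets of the
    Man9 tree containing the beta-mannose; alpha-1,2 mannoses are only
    admitted on a complete Man5 base, the canonical processing series)."""
    keys = list(MAN_SCAFFOLD)
    out = []
    for mask in range(1 << len(keys)):
        s = frozenset(keys[i] for i in range(len(keys)) if mask >> i & 1)
        if "bMan" not in s or len(s) > max_man:
            continue
        ok = True
        for k in s:
            parent = MAN_SCAFFOLD[k][0]
            if parent is not None and parent not in s:
                ok = False
                break
        if ok and (s & ALPHA2_KEYS) and not MAN5_KEYS <= s:
            ok = False
        if ok:
            out.append(s)
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


@dataclass(frozen=True)
class MotifGrammar:
    """Attachment rules and count bounds for candidate structures.

    The default N-glycan grammar encodes: Man1-9GlcNAc2 core (canonical
    mannose scaffolds); proximal GlcNAc optionally alpha-1,3- and/or
    alpha-1,6-fucosylated, distal GlcNAc optionally alpha-1,3-fucosylated;
    beta-Gal (optionally doubled) on the core alpha-1,6-fucose; alpha-Gal on
    either core alpha-1,3-fucose; bisecting beta-Gal on the beta-mannose,
    optionally carrying alpha-1,2-fucose which may be methylated; alpha-Gal
    on the alpha-1,3-mannose; and at most ``max_antennae`` HexNAc chains
    (length 1-4) on the arm mannoses with at most ``max_pc``
    phosphorylcholine groups. Tetra-antennary and anionic (HexA-containing)
    N-glycans are excluded.
    """

    mode: str = "N"  # "N" or "O"
    min_man: int = 1
    max_man: int = 9
    max_antennae: int = 3
    max_chain_len: int = 4
    max_pc: int = 2
    max_fuc: int = 5
    max_me: int = 2
    max_hexa: int = 0
    allow_core_a3_fuc: bool = True
    allow_core_a6_fuc: bool = True
    allow_distal_a3_fuc: bool = True
    allow_galfuc: bool = True
    allow_bisect: bool = True
    allow_agal_man: bool = True
    allow_antennae: bool = True
    #: core fucoses, bisect, alpha-Gal and antennae require an
    #: alpha-1,2-trimmed mannose scaffold (Golgi processing order:
    #: mannosidase I and GnT-I-dependent steps precede these decorations)
    trimmed_decorations: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("N", "O"):
            raise GrammarError(f"unknown grammar mode {self.mode!r}")


def n_glycan_grammar(**overrides) -> MotifGrammar:
    return MotifGrammar(mode="N", **overrides)


def oligomannose_grammar() -> MotifGrammar:
    """Grammar restricted to unsubstituted oligomannosidic structures
    (Man2-9GlcNAc2)."""
    return MotifGrammar(
        mode="N",
        min_man=2,
        allow_core_a3_fuc=False,
        allow_core_a6_fuc=False,
        allow_distal_a3_fuc=False,
        allow_galfuc=False,
        allow_bisect=False,
        allow_agal_man=False,
        allow_antennae=False,
    )


def o_glycan_grammar(**overrides) -> MotifGrammar:
    defaults = dict(mode="O", max_hexa=2, max_me=0, max_chain_len=3)
    defaults.update(overrides)
    return MotifGrammar(**defaults)


# ---------------------------------------------------------------------------
# N-glycan anatomy helpers
# ---------------------------------------------------------------------------


@dataclass
class NGlycanAnatomy:
    """Resolved core landmarks of an N-glycan tree (or None where absent)."""

    proximal: Node
    distal: Optional[Node]
    beta_man: Optional[Node]
    arm_a3: Optional[Node]
    arm_a6: Optional[Node]
    prox_fuc_a3: Optional[Node] = None
    prox_fuc_a6: Optional[Node] = None
    distal_fuc: Optional[Node] = None
    bisect_gal: Optional[Node] = None


def _is_man(n: Node) -> bool:
    return n.residue == "Hex" and n.identity in (None, "Man")


def resolve_anatomy(structure: GlycanStructure) -> NGlycanAnatomy:
    """Locate chitobiose core landmarks by topology and linkage."""
    prox = structure.root
    if prox.residue != "HexNAc":
        raise GrammarError("N-glycan root (proximal residue) must be HexNAc")
    distal = next((c for c in prox.children if c.residue == "HexNAc"), None)
    beta_man = None
    if distal is not None:
        beta_man = next(
            (c for c in distal.children if c.residue == "Hex" and c.anomer != "a"), None
        )
    arm_a3 = arm_a6 = None
    if beta_man is not None:
        for c in beta_man.children:
            if _is_man(c) and c.anomer == "a" and c.position == 3:
                arm_a3 = c
            elif _is_man(c) and c.anomer == "a" and c.position == 6:
                arm_a6 = c
    anat = NGlycanAnatomy(prox, distal, beta_man, arm_a3, arm_a6)
    for c in prox.children:
        if c.residue == "Fuc" and c.position == 3:
            anat.prox_fuc_a3 = c
        elif c.residue == "Fuc" and c.position == 6:
            anat.prox_fuc_a6 = c
    if distal is not None:
        anat.distal_fuc = next((c for c in distal.children if c.residue == "Fuc"), None)
    if beta_man is not None:
        anat.bisect_gal = next(
            (
                c
                for c in beta_man.children
                if c.residue == "Hex" and c.anomer == "b" and c.identity in (None, "Gal")
            ),
            None,
        )
    return anat


def _chain_nodes(head: Node) -> list[Node]:
    """Follow a linear HexNAc chain from its head; raises if it branches."""
    out = [head]
    cur = head
    while True:
        nxt = [c for c in cur.children if c.residue == "HexNAc"]
        other = [c for c in cur.children if c.residue != "HexNAc"]
        if other or len(nxt) > 1:
            raise GrammarError("antennal HexNAc chain must be linear and unsubstituted")
        if not nxt:
            return out
        cur = nxt[0]
        out.append(cur)


def arm_chains(arm: Node) -> list[list[Node]]:
    """HexNAc antenna chains attached to an arm mannose."""
    return [_chain_nodes(c) for c in arm.children if c.residue == "HexNAc"]


def antenna_chain_key(chain: list[Node]) -> str:
    """Canonical, identity-free sort key of an antennal chain (position-
    normalized); shared by the structure builder and the validator so both
    agree on the canonical arm assignment."""
    acc = ""
    for i in range(len(chain) - 1, -1, -1):
        n = chain[i]
        tok = "HexNAc" + ("+PC" if "PC" in n.substituents else "")
        link = "@b2" if i == 0 else "@b4"
        acc = tok + link + (f"({acc})" if acc else "")
    return acc


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _validate_core_fucose(fuc: Node, where: str, grammar: MotifGrammar) -> None:
    """Check a core fucose and its galactose cap against the grammar."""
    if fuc.anomer != "a":
        raise GrammarError(f"{where} core fucose must be alpha-linked")
    if fuc.substituents:
        raise GrammarError(f"{where} core fucose must be unsubstituted")
    if not grammar.allow_galfuc and fuc.children:
        raise GrammarError("galactosylated core fucose not allowed by grammar")
    if where == "proximal-a6":
        # beta-1,4-Gal, optionally extended by one more beta-Gal
        if len(fuc.children) > 1:
            raise GrammarError("alpha-1,6-fucose may carry a single galactose chain")
        if fuc.children:
            g1 = fuc.children[0]
            if g1.residue != "Hex" or g1.anomer != "b" or g1.position != 4:
                raise GrammarError("cap on alpha-1,6-fucose must be beta-1,4-galactose")
            if g1.substituents:
                raise GrammarError("GalFuc galactose must be unsubstituted")
            if len(g1.children) > 1:
                raise GrammarError("di-beta-galactosyl chain must be linear")
            if g1.children:
                g2 = g1.children[0]
                if (
                    g2.residue != "Hex"
                    or g2.anomer != "b"
                    or g2.position is not None
                    or g2.children
                    or g2.substituents
                ):
                    raise GrammarError("second galactose must be a terminal beta-Gal")
    else:
        # alpha-1,3-fucose (proximal or distal): at most one terminal alpha-Gal
        if len(fuc.children) > 1:
            raise GrammarError(f"{where} fucose carries more than one galactose")
        if fuc.children:
            g = fuc.children[0]
            if (
                g.residue != "Hex"
                or g.anomer != "a"
                or g.position is not None
                or g.children
                or g.substituents
            ):
                raise GrammarError(f"cap on {where} fucose must be a terminal alpha-Gal")


def _validate_chain(chain: list[Node], grammar: MotifGrammar) -> int:
    """Validate one antennal HexNAc chain; returns its PC count."""
    if len(chain) > grammar.max_chain_len:
        raise GrammarError("antennal chain exceeds maximum length")
    pc = 0
    for i, n in enumerate(chain):
        for s in n.substituents:
            if s != "PC":
                raise GrammarError("only PC substituents allowed on antennal HexNAc")
        pc += n.substituents.count("PC")
        if n.anomer == "a":
            raise GrammarError("antennal HexNAc must be beta-linked")
        if i == 0:
            if n.position not in (2, 4):
                raise GrammarError("chain head must be beta-1,2 or beta-1,4 linked")
        elif n.position != 4:
            raise GrammarError("chain extension must be beta-1,4 linked")
    return pc


def validate_structure(
    structure: GlycanStructure, grammar: MotifGrammar, require_core: bool = True
) -> None:
    """Raise StructureError/GrammarError unless the tree fits the grammar.

    ``require_core=False`` relaxes the chitobiose/beta-mannose completeness
    requirement (useful for residue-by-residue construction); all local
    attachment rules still apply.
    """
    nodes = structure.nodes()  # structural soundness (cycles)
    comp = composition_of(structure)
    if comp.pc > grammar.max_pc:
        raise GrammarError("too many phosphorylcholine substituents")
    if comp.me > grammar.max_me:
        raise GrammarError("too many methyl substituents")
    if comp.hexa > grammar.max_hexa:
        raise GrammarError(
            "hexuronic acid not allowed by this grammar (no anionic N-glycans)"
            if grammar.mode == "N"
            else "too many hexuronic acid residues"
        )
    if comp.fuc > grammar.max_fuc:
        raise GrammarError("too many fucose residues")
    for n in nodes:
        if "PC" in n.substituents and n.residue != "HexNAc":
            raise GrammarError("PC may only substitute HexNAc")
        if "Me" in n.substituents and n.residue != "Fuc":
            raise GrammarError("Me may only substitute fucose (grammar default)")
    if grammar.mode == "O":
        _validate_o_glycan(structure, grammar)
    else:
        _validate_n_glycan(structure, grammar, require_core)


def _validate_n_glycan(
    structure: GlycanStructure, grammar: MotifGrammar, require_core: bool = True
) -> None:
    anat = resolve_anatomy(structure)
    prox = anat.proximal
    if prox.substituents:
        raise GrammarError("proximal GlcNAc must be unsubstituted")
    allowed_ids = {id(c) for c in (anat.distal, anat.prox_fuc_a3, anat.prox_fuc_a6) if c}
    if len(prox.children) != len(allowed_ids) or any(
        id(c) not in allowed_ids for c in prox.children
    ):
        raise GrammarError("proximal GlcNAc carries a residue outside the grammar")
    if anat.prox_fuc_a3 is not None:
        if not grammar.allow_core_a3_fuc:
            raise GrammarError("core alpha-1,3-fucose not allowed")
        _validate_core_fucose(anat.prox_fuc_a3, "proximal-a3", grammar)
    if anat.prox_fuc_a6 is not None:
        if not grammar.allow_core_a6_fuc:
            raise GrammarError("core alpha-1,6-fucose not allowed")
        _validate_core_fucose(anat.prox_fuc_a6, "proximal-a6", grammar)
    if anat.distal is None:
        if require_core:
            raise GrammarError("missing distal GlcNAc (chitobiose core required)")
        return
    distal = anat.distal
    if distal.anomer != "b" or distal.position != 4:
        raise GrammarError("distal GlcNAc must be beta-1,4 linked")
    if distal.substituents:
        raise GrammarError("distal GlcNAc must be unsubstituted")
    allowed_ids = {id(c) for c in (anat.beta_man, anat.distal_fuc) if c}
    if len(distal.children) != len(allowed_ids) or any(
        id(c) not in allowed_ids for c in distal.children
    ):
        raise GrammarError("distal GlcNAc carries a residue outside the grammar")
    if anat.distal_fuc is not None:
        if not grammar.allow_distal_a3_fuc:
            raise GrammarError("distal alpha-1,3-fucose not allowed")
        if anat.distal_fuc.position not in (None, 3):
            raise GrammarError("distal fucose must be alpha-1,3-linked")
        _validate_core_fucose(anat.distal_fuc, "distal-a3", grammar)
    if anat.beta_man is None:
        if require_core:
            raise GrammarError("missing core beta-mannose (Man1GlcNAc2 minimum)")
        return
    _validate_mannose_region(anat, grammar)


def _validate_mannose_region(anat: NGlycanAnatomy, grammar: MotifGrammar) -> None:
    beta = anat.beta_man
    assert beta is not None
    if beta.substituents:
        raise GrammarError("beta-mannose must be unsubstituted")
    if beta.anomer != "b" or beta.position != 4:
        raise GrammarError("core mannose must be beta-1,4 linked")
    # map scaffold mannoses
    key_of: dict[int, str] = {id(beta): "bMan"}
    man_count = 1

    def walk(node: Node, key: str) -> None:
        nonlocal man_count
        for c in node.children:
            if not (_is_man(c) and c.anomer == "a"):
                continue
            child_key = None
            for k, (pk, _an, pos) in MAN_SCAFFOLD.items():
                if pk == key and pos == c.position:
                    child_key = k
                    break
            if child_key is None:
                raise GrammarError("mannose outside the canonical Man9 scaffold")
            if any(v == child_key for v in key_of.values()):
                raise GrammarError("duplicate mannose scaffold position")
            key_of[id(c)] = child_key
            man_count += 1
            walk(c, child_key)

    walk(beta, "bMan")
    scaffold = frozenset(key_of.values())
    if man_count > grammar.max_man:
        raise GrammarError("too many mannoses")
    if man_count < grammar.min_man:
        raise GrammarError("too few mannoses for this grammar")
    if (scaffold & ALPHA2_KEYS) and not MAN5_KEYS <= scaffold:
        raise GrammarError("alpha-1,2-mannose requires a complete Man5 base")
    if grammar.trimmed_decorations and scaffold & ALPHA2_KEYS:
        if anat.prox_fuc_a3 or anat.prox_fuc_a6 or anat.distal_fuc:
            raise GrammarError("core fucosylation requires a trimmed scaffold")
    # bisecting galactose
    if anat.bisect_gal is not None:
        if not grammar.allow_bisect:
            raise GrammarError("bisecting galactose not allowed")
        if grammar.trimmed_decorations and scaffold & ALPHA2_KEYS:
            raise GrammarError("bisecting galactose requires a trimmed scaffold")
        g = anat.bisect_gal
        if g.position != 4:
            raise GrammarError("bisecting galactose must be beta-1,4 linked")
        if g.substituents:
            raise GrammarError("bisecting galactose must be unsubstituted")
        if len(g.children) > 1:
            raise GrammarError("bisecting galactose carries too many residues")
        if g.children:
            f = g.children[0]
            if f.residue != "Fuc" or f.anomer == "b" or f.position not in (None, 2):
                raise GrammarError("bisecting galactose may only carry alpha-1,2-fucose")
            if f.children:
                raise GrammarError("bisect fucose must be terminal")
            if any(s != "Me" for s in f.substituents) or f.substituents.count("Me") > 1:
                raise GrammarError("bisect fucose may carry at most one methyl group")
    # beta-man children accounted for?
    allowed_children = {id(c) for c in beta.children if id(c) in key_of}
    if anat.bisect_gal is not None:
        allowed_children.add(id(anat.bisect_gal))
    for c in beta.children:
        if id(c) not in allowed_children:
            raise GrammarError("beta-mannose carries a residue outside the grammar")
    # arm decorations: walk each scaffold mannose's non-mannose children
    chains: list[tuple[str, list[Node]]] = []

    def inspect(node: Node, key: str) -> None:
        man_children = [c for c in node.children if id(c) in key_of]
        others = [c for c in node.children if id(c) not in key_of]
        if key == "bMan" and anat.bisect_gal is not None:
            others = [c for c in others if c is not anat.bisect_gal]
        agal = [
            c
            for c in others
            if c.residue == "Hex" and c.anomer == "a" and c.identity in (None, "Gal")
        ]
        hexnac = [c for c in others if c.residue == "HexNAc"]
        if len(agal) + len(hexnac) != len(others):
            raise GrammarError(f"mannose {key} carries a residue outside the grammar")
        if agal:
            if key != "a3" or not grammar.allow_agal_man:
                raise GrammarError("alpha-Gal only allowed on the alpha-1,3-mannose")
            if grammar.trimmed_decorations and scaffold & ALPHA2_KEYS:
                raise GrammarError("alpha-Gal on mannose requires a trimmed scaffold")
            if len(agal) > 1 or agal[0].children or agal[0].substituents:
                raise GrammarError("alpha-Gal on mannose must be single and terminal")
            if man_children or hexnac:
                raise GrammarError("alpha-galactosylated mannose must be otherwise terminal")
        if hexnac:
            if not grammar.allow_antennae:
                raise GrammarError("antennae not allowed by grammar")
            if grammar.trimmed_decorations and scaffold & ALPHA2_KEYS:
                raise GrammarError("antennae require a trimmed scaffold")
            if key not in ("a3", "a6"):
                raise GrammarError("antennae only on the core arm mannoses")
            if key == "a6" and "a3" not in scaffold:
                # canonical form: a chain-bearing solitary arm is alpha-1,3
                raise GrammarError(
                    "antennae on a solitary alpha-1,6 arm (canonical form "
                    "places them on the alpha-1,3 arm)"
                )
            if man_children:
                raise GrammarError("antenna on an extended arm mannose")
            if len(hexnac) > 2:
                raise GrammarError("more than two antennae on one arm")
            head_positions = sorted(h.position for h in hexnac if h.position)
            if head_positions not in ([], [2], [2, 4]):
                raise GrammarError(
                    "arm chains must occupy the beta-1,2 slot first, then beta-1,4"
                )
            if len(hexnac) == 2:
                by_pos = {h.position: h for h in hexnac}
                if 2 in by_pos and 4 in by_pos:
                    k2 = antenna_chain_key(_chain_nodes(by_pos[2]))
                    k4 = antenna_chain_key(_chain_nodes(by_pos[4]))
                    if k4 > k2:
                        # slot occupancy is mass-indistinguishable: canonical
                        # form puts the larger chain in the beta-1,2 slot
                        raise GrammarError("non-canonical chain slot order")
            for h in hexnac:
                chains.append((key, _chain_nodes(h)))
        for c in man_children:
            inspect(c, key_of[id(c)])

    inspect(beta, "bMan")
    if len(chains) > grammar.max_antennae:
        raise GrammarError("more than three antennae (tetra-antennary excluded)")
    for _, chain in chains:
        _validate_chain(chain, grammar)
    # canonical arm assignment: when both arms are chain-eligible, the
    # lexicographically larger chain group sits on the alpha-1,3 arm
    a3_eligible = (
        anat.arm_a3 is not None
        and "a3.2" not in scaffold
        and not any(
            c.residue == "Hex" and c.anomer == "a" for c in anat.arm_a3.children
        )
    )
    a6_eligible = anat.arm_a6 is not None and not ({"a63", "a66"} & scaffold)
    if a3_eligible and a6_eligible:
        ser_a3 = sorted(
            (antenna_chain_key(c) for arm, c in chains if arm == "a3"), reverse=True
        )
        ser_a6 = sorted(
            (antenna_chain_key(c) for arm, c in chains if arm == "a6"), reverse=True
        )
        if ser_a6 > ser_a3:
            raise GrammarError(
                "non-canonical antenna assignment (larger group belongs on the "
                "alpha-1,3 arm)"
            )


def _validate_o_glycan(structure: GlycanStructure, grammar: MotifGrammar) -> None:
    root = structure.root
    if root.residue != "HexNAc":
        raise GrammarError("O-glycan core must be a HexNAc (GalNAc-ol)")
    if structure.label_state != "alditol":
        raise GrammarError("O-glycan structures are reduced (alditol)")
    if root.substituents:
        raise GrammarError("O-glycan core residue must be unsubstituted")
    if len(root.children) > 2:
        raise GrammarError("O-glycan core carries too many branches")
    for c in root.children:
        if c.residue == "Hex" and c.position in (None, 3):
            _validate_core1_branch(c)
        else:
            _validate_o_chain(c, grammar)


def _validate_core1_branch(gal: Node) -> None:
    if gal.substituents:
        raise GrammarError("core-1 galactose must be unsubstituted")
    hexes = [c for c in gal.children if c.residue == "Hex"]
    fucs = [c for c in gal.children if c.residue == "Fuc"]
    if len(hexes) + len(fucs) != len(gal.children) or len(hexes) > 1 or len(fucs) > 1:
        raise GrammarError("core-1 branch outside the grammar")
    for f in fucs:
        if f.children or f.substituents:
            raise GrammarError("core-1 fucose must be terminal")
    for h in hexes:
        _validate_hex_chain(h, depth=2)


def _validate_hex_chain(h: Node, depth: int) -> None:
    if h.substituents:
        raise GrammarError("hexose extension must be unsubstituted")
    if depth <= 0 or len(h.children) > 1:
        raise GrammarError("hexose extension too long or branched")
    for c in h.children:
        if c.residue != "Hex":
            raise GrammarError("hexose chain may only contain hexoses")
        _validate_hex_chain(c, depth - 1)


def _validate_o_chain(head: Node, grammar: MotifGrammar) -> None:
    """Chain of HexNAc/HexA off the core, optionally hexose-capped."""
    cur: Optional[Node] = head
    length = 0
    while cur is not None:
        length += 1
        if length > grammar.max_chain_len + 2:
            raise GrammarError("O-glycan chain too long")
        if cur.residue == "HexA":
            if cur.substituents:
                raise GrammarError("hexuronic acid must be unsubstituted")
        elif cur.residue == "HexNAc":
            if any(s != "PC" for s in cur.substituents):
                raise GrammarError("only PC allowed on O-glycan chain HexNAc")
        elif cur.residue == "Hex":
            if cur.children or cur.substituents:
                raise GrammarError("capping hexose must be terminal")
        else:
            raise GrammarError("residue outside the O-glycan chain grammar")
        if len(cur.children) > 1:
            raise GrammarError("O-glycan chain must be linear")
        cur = cur.children[0] if cur.children else None


# ---------------------------------------------------------------------------
# motif matching
# ---------------------------------------------------------------------------


def _node_paths(structure: GlycanStructure) -> dict[int, str]:
    paths = {id(structure.root): "0"}
    stack = [(structure.root, "0")]
    while stack:
        n, p = stack.pop()
        for i, c in enumerate(n.children):
            cp = f"{p}.{i}"
            paths[id(c)] = cp
            stack.append((c, cp))
    return paths


def match_motifs(structure: GlycanStructure, grammar: MotifGrammar) -> list[tuple[str, str]]:
    """Named motif occurrences as (motif name, preorder location path).

    The vocabulary covers the *C. elegans* core and antennal motif summary:
    core fucoses and their galactose caps, bisecting galactose with optional
    (methyl)fucose, alpha-Gal on mannose, antennal HexNAc chains, LacdiNAc
    chain termini (mass-level: any terminal HexNAc-HexNAc pair), and
    phosphorylcholine substituents.
    """
    validate_structure(structure, grammar)
    paths = _node_paths(structure)
    out: list[tuple[str, str]] = []
    if grammar.mode == "O":
        for n in structure.nodes():
            if "PC" in n.substituents:
                out.append(("PC-HexNAc", paths[id(n)]))
            if n.residue == "HexA":
                kind = "terminal" if not n.children else "subterminal"
                out.append((f"HexA-{kind}", paths[id(n)]))
        out.sort(key=lambda t: t[1])
        return out
    anat = resolve_anatomy(structure)
    if anat.prox_fuc_a3 is not None:
        out.append(("core-a3-fucose", paths[id(anat.prox_fuc_a3)]))
        if anat.prox_fuc_a3.children:
            out.append(("aGalFuc-core", paths[id(anat.prox_fuc_a3.children[0])]))
    if anat.prox_fuc_a6 is not None:
        out.append(("core-a6-fucose", paths[id(anat.prox_fuc_a6)]))
        if anat.prox_fuc_a6.children:
            g1 = anat.prox_fuc_a6.children[0]
            out.append(("GalFuc-core", paths[id(g1)]))
            if g1.children:
                out.append(("diGalFuc-core", paths[id(g1.children[0])]))
    if anat.distal_fuc is not None:
        out.append(("distal-a3-fucose", paths[id(anat.distal_fuc)]))
        if anat.distal_fuc.children:
            out.append(("distal-GalFuc", paths[id(anat.distal_fuc.children[0])]))
    if anat.bisect_gal is not None:
        out.append(("bisecting-Gal", paths[id(anat.bisect_gal)]))
        if anat.bisect_gal.children:
            f = anat.bisect_gal.children[0]
            if "Me" in f.substituents:
                out.append(("bisecting-MeFuc", paths[id(f)]))
            else:
                out.append(("bisecting-Fuc", paths[id(f)]))
    for arm in (anat.arm_a3, anat.arm_a6):
        if arm is None:
            continue
        for c in arm.children:
            if c.residue == "Hex" and c.anomer == "a":
                out.append(("aGal-mannose", paths[id(c)]))
            elif c.residue == "HexNAc":
                chain = _chain_nodes(c)
                pc = sum(n.substituents.count("PC") for n in chain)
                out.append((f"antenna:N{len(chain)}P{pc}", paths[id(c)]))
                if len(chain) >= 2:
                    out.append(("LacdiNAc", paths[id(chain[-1])]))
                if len(chain) >= 3:
                    out.append(("chito-oligomer", paths[id(c)]))
    for n in structure.nodes():
        if "PC" in n.substituents:
            out.append(("PC-HexNAc", paths[id(n)]))
    out.sort(key=lambda t: tuple(int(x) for x in t[1].split(".")))
    return out
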