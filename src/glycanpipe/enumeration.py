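"""Grammar-constrained construction and exhaustive enumeration of candidate
glycan structures for an assigned composition.

A structure is described by a set of discrete grammar choices (mannose
scaffold, core fucosylation and galactosylation, bisect, antennae with PC
placement); both the candidate enumerator here and the synthetic-structure
sampler build trees through the same ``build_n_glycan``/``build_o_glycan``
helpers, so sampled structures are guaranteed to lie inside the enumerated
space. Enumeration is exhaustive up to grammar symmetries: isomorphic trees
are deduplicated on the canonical serialization and arm-symmetric antenna
assignments are emitted once (canonical assignment, larger group on the
alpha-1,3 arm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .model import (
    ALPHA2_KEYS,
    Composition,
    GlycanStructure,
    MAN_SCAFFOLD,
    MotifGrammar,
    Node,
    mannose_scaffolds,
)

__all__ = [
    "AntennaChain",
    "NGlycanChoices",
    "OGlycanChoices",
    "build_n_glycan",
    "build_o_glycan",
    "CandidateSet",
    "enumerate_candidates",
]


@dataclass(frozen=True)
class AntennaChain:
    """A linear antennal HexNAc chain: length, 0-based PC positions counted
    from the arm mannose outwards, and the optional epimer identity of the
    terminal residue (GalNAc marks a LacdiNAc terminus; None = unknown)."""

    length: int
    pc: frozenset[int] = frozenset()
    terminal: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chain length must be >= 1")
        if any(p < 0 or p >= self.length for p in self.pc):
            raise ValueError("PC position outside chain")
        if self.terminal not in (None, "GlcNAc", "GalNAc"):
            raise ValueError("terminal identity must be GlcNAc/GalNAc/None")

    def build(self, anomer: str = "b", position: int = 2) -> Node:
        head: Optional[Node] = None
        prev: Optional[Node] = None
        for i in range(self.length):
            last = i == self.length - 1
            identity = self.terminal if last and self.length >= 2 else "GlcNAc"
            node = Node(
                "HexNAc",
                identity,
                ("PC",) if i in self.pc else (),
                anomer if i == 0 else "b",
                position if i == 0 else 4,
            )
            if head is None:
                head = node
            else:
                assert prev is not None
                prev.add(node)
            prev = node
        assert head is not None
        return head


@dataclass(frozen=True)
class NGlycanChoices:
    """Discrete grammar decisions fully describing one N-glycan structure."""

    scaffold: frozenset[str]
    prox_a3: bool = False
    prox_a3_gal: bool = False
    prox_a6: bool = False
    a6_gal: int = 0  # 0 = bare, 1 = GalFuc, 2 = di-beta-galactosyl
    distal_fuc: bool = False
    distal_gal: bool = False
    bisect: Optional[str] = None  # 'Gal' | 'GalFuc' | 'GalFucMe'
    agal_a3: bool = False
    chains_a3: tuple[AntennaChain, ...] = ()
    chains_a6: tuple[AntennaChain, ...] = ()
    label_state: str = "PA"

    def composition(self) -> Composition:
        hex_ = (
            len(self.scaffold)
            + (1 if self.prox_a3_gal else 0)
            + self.a6_gal
            + (1 if self.distal_gal else 0)
            + (1 if self.bisect else 0)
            + (1 if self.agal_a3 else 0)
        )
        chains = self.chains_a3 + self.chains_a6
        hexnac = 2 + sum(c.length for c in chains)
        fuc = (
            (1 if self.prox_a3 else 0)
            + (1 if self.prox_a6 else 0)
            + (1 if self.distal_fuc else 0)
            + (1 if self.bisect in ("GalFuc", "GalFucMe") else 0)
        )
        me = 1 if self.bisect == "GalFucMe" else 0
        pc = sum(len(c.pc) for c in chains)
        return Composition(hex_, hexnac, fuc, 0, me, pc, self.label_state)


def _chain_sort_key(chain: AntennaChain) -> str:
    return chain.build().serialize(with_identity=False, _root=False)


def arm_eligibility(choices: NGlycanChoices) -> tuple[bool, bool]:
    """Which arm mannoses may carry antennae, given scaffold and alpha-Gal.

    A solitary unextended arm mannose carrying antennae is canonically the
    alpha-1,3 arm: with the alpha-1,3 arm absent the swapped variant is
    indistinguishable by mass spectrometry, so the alpha-1,6 arm is only
    chain-eligible when the alpha-1,3 mannose is present.
    """
    s = choices.scaffold
    a3 = "a3" in s and "a3.2" not in s and not choices.agal_a3
    a6 = "a6" in s and "a3" in s and not ({"a63", "a66"} & s)
    return a3, a6


def build_n_glycan(choices: NGlycanChoices) -> GlycanStructure:
    """Materialize grammar choices as a glycan tree.

    When both arms are antenna-eligible the chain groups are swapped if
    needed so that the canonically larger group sits on the alpha-1,3 arm.
    """
    prox = Node("HexNAc", "GlcNAc")
    distal = Node("HexNAc", "GlcNAc", (), "b", 4)
    prox.add(distal)
    if choices.prox_a3:
        f = Node("Fuc", "Fuc", (), "a", 3)
        if choices.prox_a3_gal:
            f.add(Node("Hex", "Gal", (), "a", None))
        prox.add(f)
    if choices.prox_a6:
        f = Node("Fuc", "Fuc", (), "a", 6)
        if choices.a6_gal >= 1:
            g1 = Node("Hex", "Gal", (), "b", 4)
            if choices.a6_gal >= 2:
                g1.add(Node("Hex", "Gal", (), "b", None))
            f.add(g1)
        prox.add(f)
    if choices.distal_fuc:
        f = Node("Fuc", "Fuc", (), "a", 3)
        if choices.distal_gal:
            f.add(Node("Hex", "Gal", (), "a", None))
        distal.add(f)

    man_nodes: dict[str, Node] = {}
    if "bMan" in choices.scaffold:
        man_nodes["bMan"] = Node("Hex", "Man", (), "b", 4)
        distal.add(man_nodes["bMan"])
        for key in sorted(choices.scaffold - {"bMan"}):
            parent_key, anomer, position = MAN_SCAFFOLD[key]
            man_nodes[key] = Node("Hex", "Man", (), anomer, position)
        # attach in scaffold order (parents before children by key sorting
        # is not guaranteed, so attach by lookup)
        for key in sorted(choices.scaffold - {"bMan"}, key=lambda k: len(k)):
            parent_key = MAN_SCAFFOLD[key][0]
            assert parent_key is not None
            man_nodes[parent_key].add(man_nodes[key])
        if choices.bisect:
            g = Node("Hex", "Gal", (), "b", 4)
            if choices.bisect in ("GalFuc", "GalFucMe"):
                subs = ("Me",) if choices.bisect == "GalFucMe" else ()
                g.add(Node("Fuc", "Fuc", subs, "a", 2))
            man_nodes["bMan"].add(g)
        if choices.agal_a3:
            man_nodes["a3"].add(Node("Hex", "Gal", (), "a", None))
        a3_ok, a6_ok = arm_eligibility(choices)
        chains_a3 = sorted(choices.chains_a3, key=_chain_sort_key, reverse=True)
        chains_a6 = sorted(choices.chains_a6, key=_chain_sort_key, reverse=True)
        if a3_ok and a6_ok:
            # descending chain-key lists, consistent with the validator's
            # canonical arm-assignment check
            key_a3 = [_chain_sort_key(c) for c in chains_a3]
            key_a6 = [_chain_sort_key(c) for c in chains_a6]
            if key_a6 > key_a3:
                chains_a3, chains_a6 = chains_a6, chains_a3
        for chains, key in ((chains_a3, "a3"), (chains_a6, "a6")):
            for i, chain in enumerate(chains):
                man_nodes[key].add(chain.build(position=2 if i == 0 else 4))
    structure = GlycanStructure(prox, choices.label_state)
    return structure


# ---------------------------------------------------------------------------
# O-glycans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OGlycanChoices:
    """Mucin-type O-glycan: GalNAc-ol core with optional core-1 galactose
    branch (fucosylated/extended) and one linear chain of HexNAc (+-PC) and
    HexA units, optionally capped by a hexose."""

    core1: bool = False
    core1_fuc: bool = False
    core1_ext: int = 0  # extra hexoses on the core-1 galactose (0-2)
    chain: tuple[str, ...] = ()  # tokens: 'HexNAc', 'HexNAc+PC', 'HexA'
    cap_hex: bool = False

    def composition(self) -> Composition:
        hex_ = (1 if self.core1 else 0) + self.core1_ext + (1 if self.cap_hex else 0)
        hexnac = 1 + sum(1 for t in self.chain if t.startswith("HexNAc"))
        hexa = sum(1 for t in self.chain if t == "HexA")
        pc = sum(1 for t in self.chain if t == "HexNAc+PC")
        fuc = 1 if self.core1_fuc else 0
        return Composition(hex_, hexnac, fuc, hexa, 0, pc, "alditol")


def build_o_glycan(choices: OGlycanChoices) -> GlycanStructure:
    root = Node("HexNAc", "GalNAc")
    if choices.core1:
        gal = Node("Hex", "Gal", (), "b", 3)
        root.add(gal)
        if choices.core1_fuc:
            gal.add(Node("Fuc", "Fuc", (), "a", 2))
        cur = gal
        for _ in range(choices.core1_ext):
            nxt = Node("Hex", None, (), "b", None)
            cur.add(nxt)
            cur = nxt
    if choices.chain:
        prev: Node = root
        for i, token in enumerate(choices.chain):
            if token == "HexA":
                node = Node("HexA", "GlcA", (), "b", None)
            elif token in ("HexNAc", "HexNAc+PC"):
                node = Node(
                    "HexNAc",
                    "GlcNAc",
                    ("PC",) if token.endswith("+PC") else (),
                    "b",
                    6 if i == 0 else 4,
                )
            else:
                raise ValueError(f"unknown chain token {token!r}")
            prev.add(node)
            prev = node
        if choices.cap_hex:
            prev.add(Node("Hex", None, (), "b", None))
    elif choices.cap_hex:
        raise ValueError("cap_hex requires a chain")
    return GlycanStructure(root, "alditol")


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


@dataclass
class CandidateSet:
    """Result of candidate enumeration for one composition."""

    structures: list[GlycanStructure] = field(default_factory=list)
    truncated: bool = False
    reason: Optional[str] = None

    def __len__(self) -> int:
        return len(self.structures)


def _bisect_options(grammar: MotifGrammar, comp: Composition) -> list[Optional[str]]:
    opts: list[Optional[str]] = [None]
    if grammar.allow_bisect and comp.hex >= 1:
        opts.append("Gal")
        if comp.fuc >= 1:
            opts.append("GalFuc")
            if comp.me >= 1:
                opts.append("GalFucMe")
    return opts


def _chain_length_multisets(total: int, max_chains: int, max_len: int) -> list[tuple[int, ...]]:
    """Non-increasing tuples of chain lengths summing to ``total``."""
    out: list[tuple[int, ...]] = []

    def rec(remaining: int, max_part: int, acc: tuple[int, ...]) -> None:
        if remaining == 0:
            out.append(acc)
            return
        if len(acc) >= max_chains:
            return
        for part in range(min(remaining, max_part), 0, -1):
            rec(remaining - part, part, acc + (part,))

    rec(total, max_len, ())
    return out


def _decorated_chain_sets(
    lengths: tuple[int, ...], n_pc: int
) -> Iterator[tuple[AntennaChain, ...]]:
    """All PC placements of ``n_pc`` groups over chains with the given
    lengths, deduplicated over permutations of identical chains."""
    positions = [(ci, pos) for ci, ln in enumerate(lengths) for pos in range(ln)]
    seen: set[tuple[str, ...]] = set()
    for combo in itertools.combinations(positions, n_pc):
        pcs: dict[int, set[int]] = {ci: set() for ci in range(len(lengths))}
        for ci, pos in combo:
            pcs[ci].add(pos)
        chains = tuple(
            AntennaChain(ln, frozenset(pcs[ci])) for ci, ln in enumerate(lengths)
        )
        key = tuple(sorted(_chain_sort_key(c) for c in chains))
        if key in seen:
            continue
        seen.add(key)
        yield tuple(sorted(chains, key=_chain_sort_key, reverse=True))


def _arm_assignments(
    chains: tuple[AntennaChain, ...], a3_ok: bool, a6_ok: bool
) -> Iterator[tuple[tuple[AntennaChain, ...], tuple[AntennaChain, ...]]]:
    """Distribute a chain multiset over the eligible arms (<=2 per arm).

    When both arms are eligible only canonical assignments (larger group on
    the alpha-1,3 arm) are yielded; mass spectra cannot distinguish the
    swapped variant.
    """
    n = len(chains)
    if n == 0:
        yield (), ()
        return
    if a3_ok and not a6_ok:
        if n <= 2:
            yield chains, ()
        return
    if a6_ok and not a3_ok:
        if n <= 2:
            yield (), chains
        return
    if not (a3_ok or a6_ok):
        return
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for mask in range(1 << n):
        g3 = tuple(chains[i] for i in range(n) if mask >> i & 1)
        g6 = tuple(chains[i] for i in range(n) if not mask >> i & 1)
        if len(g3) > 2 or len(g6) > 2:
            continue
        k3 = sorted((_chain_sort_key(c) for c in g3), reverse=True)
        k6 = sorted((_chain_sort_key(c) for c in g6), reverse=True)
        if k6 > k3:
            continue  # non-canonical: swapped variant is indistinguishable
        key = (tuple(k3), tuple(k6))
        if key in seen:
            continue
        seen.add(key)
        yield g3, g6


def _enumerate_n_choices(
    comp: Composition, grammar: MotifGrammar
) -> Iterator[NGlycanChoices]:
    if comp.hexnac < 2 or comp.hex < 1:
        return
    for scaffold in mannose_scaffolds(grammar.max_man):
        n_man = len(scaffold)
        if n_man > comp.hex or n_man < grammar.min_man:
            continue
        trimmed = not (grammar.trimmed_decorations and scaffold & ALPHA2_KEYS)
        for bisect in _bisect_options(grammar, comp) if trimmed else (None,):
            for prox_a3 in (
                (False, True) if grammar.allow_core_a3_fuc and trimmed else (False,)
            ):
                for prox_a6 in (
                    (False, True) if grammar.allow_core_a6_fuc and trimmed else (False,)
                ):
                    for distal_fuc in (
                        (False, True)
                        if grammar.allow_distal_a3_fuc and trimmed
                        else (False,)
                    ):
                        gal_opts_a3 = (False, True) if (prox_a3 and grammar.allow_galfuc) else (False,)
                        gal_opts_a6 = (0, 1, 2) if (prox_a6 and grammar.allow_galfuc) else (0,)
                        gal_opts_d = (False, True) if (distal_fuc and grammar.allow_galfuc) else (False,)
                        agal_opts = (
                            (False, True)
                            if (
                                grammar.allow_agal_man
                                and trimmed
                                and "a3" in scaffold
                                and "a3.2" not in scaffold
                            )
                            else (False,)
                        )
                        for prox_a3_gal in gal_opts_a3:
                            for a6_gal in gal_opts_a6:
                                for distal_gal in gal_opts_d:
                                    for agal in agal_opts:
                                        yield from _finish_n_choices(
                                            comp,
                                            grammar,
                                            scaffold,
                                            bisect,
                                            prox_a3,
                                            prox_a3_gal,
                                            prox_a6,
                                            a6_gal,
                                            distal_fuc,
                                            distal_gal,
                                            agal,
                                        )


def _finish_n_choices(
    comp, grammar, scaffold, bisect, prox_a3, prox_a3_gal, prox_a6, a6_gal,
    distal_fuc, distal_gal, agal,
) -> Iterator[NGlycanChoices]:
    used_fuc = int(prox_a3) + int(prox_a6) + int(distal_fuc)
    used_me = 0
    used_hex = len(scaffold) + int(prox_a3_gal) + a6_gal + int(distal_gal) + int(agal)
    if bisect:
        used_hex += 1
        if bisect in ("GalFuc", "GalFucMe"):
            used_fuc += 1
        if bisect == "GalFucMe":
            used_me = 1
    if used_fuc != comp.fuc or used_me != comp.me or used_hex != comp.hex:
        return
    rem_hexnac = comp.hexnac - 2
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
        label_state=comp.label_state,
    )
    a3_ok, a6_ok = arm_eligibility(base)
    if rem_hexnac == 0:
        if comp.pc == 0:
            yield base
        return
    if not grammar.allow_antennae or not (a3_ok or a6_ok):
        return
    if grammar.trimmed_decorations and scaffold & ALPHA2_KEYS:
        return
    max_chains = min(grammar.max_antennae, (2 if a3_ok else 0) + (2 if a6_ok else 0))
    for lengths in _chain_length_multisets(rem_hexnac, max_chains, grammar.max_chain_len):
        if comp.pc > sum(lengths):
            continue
        for chains in _decorated_chain_sets(lengths, comp.pc):
            for g3, g6 in _arm_assignments(chains, a3_ok, a6_ok):
                yield NGlycanChoices(
                    scaffold=scaffold,
                    prox_a3=prox_a3,
                    prox_a3_gal=prox_a3_gal,
                    prox_a6=prox_a6,
                    a6_gal=a6_gal,
                    distal_fuc=distal_fuc,
                    distal_gal=distal_gal,
                    bisect=bisect,
                    agal_a3=agal,
                    chains_a3=g3,
                    chains_a6=g6,
                    label_state=comp.label_state,
                )


def _enumerate_o_choices(
    comp: Composition, grammar: MotifGrammar
) -> Iterator[OGlycanChoices]:
    if comp.hexnac < 1 or comp.me > 0:
        return
    rem_hexnac = comp.hexnac - 1
    for core1 in (False, True) if comp.hex >= 1 or comp.hex == 0 else (False,):
        for core1_fuc in (False, True) if core1 and comp.fuc >= 1 else (False,):
            for core1_ext in range(0, 3):
                if core1_ext and not core1:
                    continue
                for cap_hex in (False, True):
                    used_hex = int(core1) + core1_ext + int(cap_hex)
                    if used_hex != comp.hex:
                        continue
                    if int(core1_fuc) != comp.fuc:
                        continue
                    # chains: sequences of HexNAc(+-PC)/HexA
                    chain_len = rem_hexnac + comp.hexa
                    if chain_len == 0:
                        if comp.pc == 0 and not cap_hex:
                            yield OGlycanChoices(core1, core1_fuc, core1_ext, (), False)
                        continue
                    if chain_len > grammar.max_chain_len + 2:
                        continue
                    for hexa_pos in itertools.combinations(range(chain_len), comp.hexa):
                        nac_slots = [i for i in range(chain_len) if i not in hexa_pos]
                        for pc_slots in itertools.combinations(nac_slots, comp.pc):
                            tokens = []
                            for i in range(chain_len):
                                if i in hexa_pos:
                                    tokens.append("HexA")
                                elif i in pc_slots:
                                    tokens.append("HexNAc+PC")
                                else:
                                    tokens.append("HexNAc")
                            yield OGlycanChoices(
                                core1, core1_fuc, core1_ext, tuple(tokens), cap_hex
                            )


def enumerate_candidates(
    comp: Composition, grammar: MotifGrammar, cap: int = 10_000
) -> CandidateSet:
    """All grammar-consistent structures with the given composition.

    Exhaustive up to grammar symmetries; isomorphic duplicates removed on
    the canonical serialization; enumeration stops (``truncated=True``) at
    ``cap`` candidates. Compositions outside the grammar return an empty
    set with an explanatory ``reason``.
    """
    out = CandidateSet()
    if grammar.mode == "N":
        if comp.hexa > 0:
            out.reason = "hexuronic acid excluded: no anionic N-glycans in this grammar"
            return out
        if comp.label_state == "alditol":
            out.reason = "alditol label state is an O-glycan feature"
            return out
        if comp.hexnac < 2 or comp.hex < 1:
            out.reason = "composition below the Man1GlcNAc2 chitobiose core"
            return out
        gen = _enumerate_n_choices(comp, grammar)
        builder = build_n_glycan
    else:
        if comp.label_state != "alditol":
            out.reason = "O-glycan candidates require the alditol label state"
            return out
        if comp.me > 0:
            out.reason = "methylation excluded from the O-glycan grammar"
            return out
        gen = _enumerate_o_choices(comp, grammar)
        builder = build_o_glycan
    seen: set[str] = set()
    for choices in gen:
        if choices.composition() != comp:
            continue
        structure = builder(choices)
        key = structure.canonical()
        if key in seen:
            continue
        seen.add(key)
        out.structures.append(structure)
        if len(out.structures) >= cap:
            out.truncated = True
            break
    out.structures.sort(key=lambda s: s.canonical())
    if not out.structures and out.reason is None:
        out.reason = "no grammar-consistent structure for this composition"
    return out
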