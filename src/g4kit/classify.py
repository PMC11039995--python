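"""Topology, gc patterns, loops, stacking types and platypus detection.

The topology of a one-block stem is the 4-letter down/up code of its
strands (strand 1 is down by construction), one of eight named classes:

    dddd parallel          dudu antiparallel-chair
    duud antiparallel-basket   dduu antiparallel-basket2
    ddud hybrid1           dddu hybrid2
    dudd hybrid3           duuu hybrid4

Each topology carries a predominant gc pattern (same-direction neighbours
share their gc, opposite-direction neighbours alternate) and a
groove-width signature, which is why a single clean tetrad suffices to
deduce the topology.  Structures whose characteristics disagree --
directions saying one topology, gc pattern or measured widths another --
are the platypus cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import signed_angle
from .geom import GrooveProfile, threshold_signature
from .glyco import GcRecord
from .io import StructureModel
from .stem import Stem
from .synthgen import TOPOLOGY_BY_CODE, block_topology_name, signature_from_directions

__all__ = [
    "TopologyCall",
    "LoopAnnotation",
    "Loop",
    "StackingTypeCall",
    "PlatypusReport",
    "topology",
    "gc_pattern",
    "topology_from_single_tetrad",
    "annotate_loops",
    "stacking_types",
    "platypus_check",
    "SIGNATURE_TO_TOPOLOGY",
    "LOOPS_TO_TOPOLOGY",
]


#: Groove-width signature -> candidate topologies (basket2 has two
#: signatures; iwii is its long-RNA variant).
SIGNATURE_TO_TOPOLOGY = {
    "iiii": {"parallel"},
    "wnwn": {"antiparallel-chair"},
    "wini": {"antiparallel-basket"},
    "iwin": {"antiparallel-basket2"},
    "iwii": {"antiparallel-basket2"},
    "iwni": {"hybrid1"},
    "iiwn": {"hybrid2"},
    "wnii": {"hybrid3"},
    "wiin": {"hybrid4"},
}

#: Basic loop combination -> topologies in which it is observed.
LOOPS_TO_TOPOLOGY = {
    "-p-p-p": {"parallel"},
    "+l+l+l": {"antiparallel-chair"},
    "-l-l-l": {"antiparallel-chair"},
    "-ld+l": {"antiparallel-basket"},
    "d+pd": {"antiparallel-basket"},
    "-pd+p": {"antiparallel-basket2"},
    "+ld-l": {"antiparallel-basket2"},
    "+l+p+l": {"antiparallel-basket2", "hybrid3"},
    "-p-l-l": {"hybrid1"},
    "-p-l-p": {"hybrid1"},
    "-pd+l": {"hybrid2"},
    "-p-p-l": {"hybrid2", "parallel"},
    "-l-p-l": {"hybrid2"},
    "-l-l-p": {"hybrid3"},
    "+l+p+p": {"hybrid4"},
    "+p+l+p": {"hybrid4"},
    "d+p+l+p": {"hybrid4"},
}


@dataclass
class TopologyCall:
    code: str                        # "dddd" or "dddd/uuuu"
    name: str                        # "parallel" or "parallel / parallel"
    per_block: list[str] = field(default_factory=list)
    undetermined_strands: list[int] = field(default_factory=list)
    suggestion: str | None = None    # gc-based hint when undetermined


@dataclass
class Loop:
    kind: str                        # p | l | d | v | internal | snapback | other
    sign: str                        # '+' | '-' | '' (diagonals are unsigned)
    length: int                      # nucleotides in the connector
    strands: tuple[int, int]         # exit strand, entry strand
    positions: tuple[int, int]       # chain positions of flanking guanosines
    snapback: bool = False

    @property
    def token(self) -> str:
        return self.sign + self.kind


@dataclass
class LoopAnnotation:
    loops: list[Loop]

    @property
    def combination(self) -> str:
        """Chain-order combination string of the basic (non-snapback) loops."""
        return "".join(l.token for l in self.loops if not l.snapback)

    @property
    def full_combination(self) -> str:
        return "".join(
            (f"*{l.token}*" if l.snapback else l.token) for l in self.loops)


@dataclass
class StackingTypeCall:
    per_strand: dict[int, int]       # strand -> 1 | 2 | 3
    successions: dict[int, str]      # strand -> e.g. "saa" (chain order)
    two_tetrad_note: bool = False    # the 3-type scheme collapses at T=2


@dataclass
class PlatypusReport:
    implied: dict[str, set[str]]     # characteristic -> topology set
    is_platypus: bool
    consistent: set[str]


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _block_directions(stem: Stem, lo: int, hi: int) -> str:
    """Strand direction letters within one block, from chain progression."""
    letters = []
    for s in stem.strands:
        if s.direction == "undetermined" and any(
                d.kind == "cross_chain" for d in s.discontinuities):
            letters.append("?")
            continue
        ranks = [stem.model.chain_rank(g) for g in s.guanosines[lo - 1:hi]]
        if len(ranks) < 2:
            letters.append("-")
            continue
        steps = [b - a for a, b in zip(ranks, ranks[1:])]
        votes = [x for x in steps if abs(x) == 1] or steps
        total = sum(np.sign(x) for x in votes)
        letters.append("d" if total > 0 else "u" if total < 0 else "?")
    return "".join(letters)


def topology(stem: Stem, gc_records: dict[tuple, GcRecord] | None = None) -> TopologyCall:
    """Topology call per block from the strand directions."""
    per_block = [_block_directions(stem, lo, hi) for lo, hi in stem.blocks]
    undetermined = sorted({
        i + 1 for code in per_block for i, c in enumerate(code) if c == "?"
    })
    names = []
    for code in per_block:
        if all(c == "-" for c in code):
            names.append("-")                     # one-tetrad block
        elif "?" in code:
            names.append("undetermined")
        else:
            names.append(block_topology_name(code))
    call = TopologyCall(
        code="/".join(per_block),
        name=" / ".join(names),
        per_block=per_block,
        undetermined_strands=undetermined,
    )
    if undetermined and gc_records:
        # the gc pattern gives the hint about the topology
        patterns = gc_pattern(stem, gc_records)["patterns"]
        clean = [p for p in patterns if "?" not in p]
        if clean:
            try:
                call.suggestion = topology_from_single_tetrad(clean[0]).name
            except ValueError:
                pass
    return call


def gc_pattern(stem: Stem, gc_records: dict[tuple, GcRecord]) -> dict:
    """Per-tetrad 4-letter s/a strings (strand order 1-4) plus the
    predicted pattern pair for the topology and a mismatch report."""
    patterns = []
    for t in stem.tetrads:
        letters = []
        for g in t.members_by_slot:
            rec = gc_records.get(g.key)
            letters.append(rec.letter if rec else "?")
        patterns.append("".join(letters))

    dir_letters = [s.direction for s in stem.strands]
    predicted = None
    if "undetermined" not in dir_letters:
        base = "".join(
            "a" if d == stem.strands[0].direction else "s" for d in dir_letters)
        comp = base.translate(str.maketrans("as", "sa"))
        predicted = (base, comp)

    mismatches = []
    if predicted:
        for t_index, pat in enumerate(patterns, start=1):
            if pat in predicted or "?" in pat:
                continue
            for slot in range(1, 5):
                exp = {predicted[0][slot - 1], predicted[1][slot - 1]}
                strand = stem.strands[slot - 1]
                micro = strand.micro[t_index - 1] if strand.micro else strand.direction
                if pat[slot - 1] not in exp or micro != strand.direction:
                    mismatches.append({
                        "tetrad": t_index, "strand": slot,
                        "letter": pat[slot - 1],
                        "micro_direction": micro,
                        "micro_effect": micro != strand.direction,
                    })
    return {"patterns": patterns, "predicted": predicted, "mismatches": mismatches}


def topology_from_single_tetrad(pattern: str) -> TopologyCall:
    """Deduce the topology from one clean tetrad's s/a pattern.

    Anchored at strand 1 = down: strands whose letter differs from letter
    1 run opposite to strand 1.  Each topology is hit by exactly two
    complementary patterns.
    """
    if len(pattern) != 4 or set(pattern) - {"a", "s"}:
        raise ValueError(f"need a 4-letter s/a pattern, got {pattern!r}")
    code = "".join("d" if c == pattern[0] else "u" for c in pattern)
    return TopologyCall(code=code, name=TOPOLOGY_BY_CODE[code], per_block=[code])


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

def annotate_loops(stem: Stem, model: StructureModel | None = None) -> LoopAnnotation:
    """Type the connectors between consecutive stem guanosines of
    different strands; progression sign is the rotation sense about the
    stem axis viewed bottom-to-top (clockwise +)."""
    model = model or stem.model
    rank = model.chain_rank
    where = {}
    for s in stem.strands:
        for t_index, g in enumerate(s.guanosines, start=1):
            where[rank(g)] = (s.number, t_index, g)
    snap_spans = []
    for s in stem.strands:
        for d in s.discontinuities:
            if d.kind.startswith("snapback") and d.span:
                snap_spans.append(d.span)

    order = sorted(where)
    axis_up = -stem.axis_topdown
    centroid = np.mean([t.centroid for t in stem.tetrads], axis=0)
    loops = []
    for ra, rb in zip(order, order[1:]):
        sa, ta, ga = where[ra]
        sb, tb, gb = where[rb]
        if sa == sb:
            continue  # same strand: bulge/internal handled as discontinuities
        length = rb - ra - 1
        adjacent = (sb - sa) % 4 in (1, 3)
        blocks_differ = stem.block_of_tetrad(ta) != stem.block_of_tetrad(tb)
        if blocks_differ:
            kind = "linker"
        elif ta == tb:
            kind = "l" if adjacent else "d"
        elif adjacent:
            kind = "p" if length > 0 else "v"
        else:
            kind = "other"
        if kind == "d":
            sign = ""
        else:
            v1 = ga.coord("C1'") - centroid if ga.has("C1'") else None
            v2 = gb.coord("C1'") - centroid if gb.has("C1'") else None
            if v1 is None or v2 is None:
                sign = "?"
            else:
                sign = "+" if signed_angle(v1, v2, axis_up) > 0 else "-"
        is_snap = any(lo <= rank(ga) <= hi or lo <= rank(gb) <= hi
                      for lo, hi in snap_spans)
        loops.append(Loop(kind=kind, sign=sign, length=length,
                          strands=(sa, sb), positions=(ga.position, gb.position),
                          snapback=is_snap))
    return LoopAnnotation(loops=loops)


# ---------------------------------------------------------------------------
# Stacking types
# ---------------------------------------------------------------------------

def stacking_types(stem: Stem, gc_records: dict[tuple, GcRecord]) -> StackingTypeCall:
    """Vertical gc succession class per strand, read along the chain.

    Type 1: only similar gcs; type 2: similar and alternate; type 3: only
    alternate.  Two-tetrad strands collapse to same -> 1, different -> 3.
    """
    per_strand, successions = {}, {}
    rank = stem.model.chain_rank
    for s in stem.strands:
        chain_order = sorted(s.guanosines, key=rank)
        letters = "".join(
            gc_records[g.key].letter if g.key in gc_records else "?"
            for g in chain_order)
        successions[s.number] = letters
        pairs = [(a, b) for a, b in zip(letters, letters[1:]) if "?" not in (a, b)]
        if not pairs:
            per_strand[s.number] = 0
            continue
        same = [a == b for a, b in pairs]
        if all(same):
            per_strand[s.number] = 1
        elif not any(same):
            per_strand[s.number] = 3
        else:
            per_strand[s.number] = 2
    return StackingTypeCall(
        per_strand=per_strand,
        successions=successions,
        two_tetrad_note=stem.n_tetrads == 2,
    )


# ---------------------------------------------------------------------------
# Platypus
# ---------------------------------------------------------------------------

def platypus_check(
    topology_call: TopologyCall,
    gc_report: dict,
    profile: GrooveProfile,
    loop_annotation: LoopAnnotation,
) -> PlatypusReport:
    """Cross-check the four characteristics; a platypus is a structure
    whose characteristics point at different topologies (empty
    intersection of the implied topology sets)."""
    implied: dict[str, set[str]] = {}

    if "undetermined" not in topology_call.name and "-" not in topology_call.per_block[0]:
        implied["strand_directions"] = {
            block_topology_name(topology_call.per_block[0])}

    clean = [p for p in gc_report["patterns"] if "?" not in p]
    gc_topos = set()
    for pat in clean:
        try:
            gc_topos.add(topology_from_single_tetrad(pat).name)
        except (ValueError, KeyError):
            pass
    if gc_topos:
        implied["gc_pattern"] = gc_topos

    # the threshold signature is the informative one here: the
    # direction-based letters are tautological with the topology
    sig = profile.signature_threshold
    if sig in SIGNATURE_TO_TOPOLOGY:
        implied["groove_signature"] = set(SIGNATURE_TO_TOPOLOGY[sig])

    combo = loop_annotation.combination
    if combo in LOOPS_TO_TOPOLOGY:
        implied["loops"] = set(LOOPS_TO_TOPOLOGY[combo])

    if len(implied) < 2:
        return PlatypusReport(implied=implied, is_platypus=False,
                              consistent=set().union(*implied.values()) if implied else set())
    consistent = set.intersection(*implied.values())
    return PlatypusReport(implied=implied, is_platypus=not consistent,
                          consistent=consistent)
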