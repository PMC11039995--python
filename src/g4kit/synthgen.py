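"""Idealized G-quadruplex coordinate generator with ground-truth labels.

The generator builds planar guanine tetrads whose Hoogsteen 4-cycle is
solved numerically (a small rigid-placement least squares), stacks them
with a configurable per-step twist and rise, attaches a minimal sugar
(C1', O4', C3', C5', P, O5', optionally H1'/H8) whose placement realizes
the requested glycosidic configuration (chi torsion) and strand direction,
and threads a nucleotide chain through the strands so that loops, bulges,
snapbacks and two-block gaps come out as requested.

The geometry is stylized, not energy-minimized: bases are exactly planar,
sugars are reduced to the atoms the analysis needs, and loop residues are
placeholders.  What is faithful is the formalism the analysis measures:
Hoogsteen donor->acceptor cycles, syn/anti chi values, the correspondence
between strand directions and gc patterns, groove-width classes by
adjacent strand direction (narrow ~11.4 A for up-down, medium ~15.1 A for
same-direction, wide ~17.9 A for down-up at the default radius), and the
per-step twist/rise.

A guanine's base flip state ("donors to the right over the ribose" for
syn, "to the left" for anti, looking along the strand) is what couples gc
to strand direction: within one tetrad the quantity (gc is syn) XOR
(strand goes up) must be the same for all four members, otherwise the
Hoogsteen cycle cannot close.  The generator enforces exactly that rule
and refuses inconsistent specs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from ._linalg import place_atom, unit
from .io import ExperimentKind, Residue, StructureModel, write_pdb

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "build_stem",
    "build_cohort",
    "TOPOLOGY_BY_CODE",
    "CODE_BY_TOPOLOGY",
    "SpecValidationError",
]


class SpecValidationError(ValueError):
    """The requested gc pattern / directions / discontinuities are inconsistent."""


# ---------------------------------------------------------------------------
# Topology bookkeeping
# ---------------------------------------------------------------------------

TOPOLOGY_BY_CODE = {
    "dddd": "parallel",
    "dudu": "antiparallel-chair",
    "duud": "antiparallel-basket",
    "dduu": "antiparallel-basket2",
    "ddud": "hybrid1",
    "dddu": "hybrid2",
    "dudd": "hybrid3",
    "duuu": "hybrid4",
}
CODE_BY_TOPOLOGY = {v: k for k, v in TOPOLOGY_BY_CODE.items()}

#: Chain visiting order of the strand slots realizing the most common loop
#: combination of each topology (propeller/lateral/diagonal as tabulated in
#: cohort surveys: parallel -p-p-p, chair +l+l+l, basket -ld+l, ...).
_VISIT_ORDER = {
    "dddd": (1, 2, 3, 4),
    "dudu": (1, 4, 3, 2),
    "duud": (1, 2, 4, 3),
    "dduu": (1, 2, 4, 3),
    "ddud": (1, 2, 3, 4),
    "dddu": (1, 2, 3, 4),
    "dudd": (1, 2, 3, 4),
    "duuu": (1, 4, 3, 2),
}

_DEFAULT_LOOP_LEN = {"p": 2, "l": 3, "d": 4, "v": 0}


def block_topology_name(code: str) -> str:
    """Topology name of a (possibly up-leading) block code.

    A block whose own first strand runs up is named after its complement:
    uuuu is a parallel block, just traversed the other way.
    """
    if code in TOPOLOGY_BY_CODE:
        return TOPOLOGY_BY_CODE[code]
    comp = "".join("d" if c == "u" else "u" for c in code)
    if comp in TOPOLOGY_BY_CODE:
        return TOPOLOGY_BY_CODE[comp]
    raise SpecValidationError(f"unknown topology code {code!r}")


def _canonical_parities(code: str, n_tetrads: int, phase: int) -> list[int]:
    """Per-tetrad base-flip parity giving the predominant gc pattern.

    Parity of tetrad t is (gc is syn) XOR (strand is up), identical for all
    four members.  Parallel stems: all 0 (all-anti).  Antiparallel stems:
    strict vertical alternation starting syn at the top.  Hybrids: syn top
    tetrad, anti below (the 'saa...' vertical succession).  ``phase=1``
    complements every tetrad.
    """
    name = block_topology_name(code)
    if name == "parallel":
        base = [0] * n_tetrads
    elif name.startswith("antiparallel"):
        base = [(t + 1) % 2 for t in range(n_tetrads)]  # 1,0,1,0,...
    else:  # hybrids
        base = [1] + [0] * (n_tetrads - 1)
    if phase:
        base = [1 - p for p in base]
    return base


def pattern_from_parity(code: str, parity: int) -> str:
    """4-letter s/a tetrad pattern implied by a parity and strand directions.

    parity = (gc is syn) XOR (strand is up), so syn = parity XOR up.
    """
    return "".join("s" if (parity ^ (c == "u")) else "a" for c in code)


# ---------------------------------------------------------------------------
# Guanine template and tetrad pose solving
# ---------------------------------------------------------------------------

#: Planar guanine heavy atoms, standard base reference frame (x, y in A).
_GUANINE_2D = {
    "N9": (-1.289, 4.551),
    "C8": (0.023, 4.962),
    "N7": (0.870, 3.969),
    "C5": (0.071, 2.833),
    "C6": (0.424, 1.460),
    "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641),
    "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364),
    "C4": (-1.265, 3.177),
    "C1'": (-2.477, 5.399),
}

_HBOND_N1_O6 = 2.92  # target heavy-atom distances of the Hoogsteen pair
_HBOND_N2_N7 = 2.86
_O6_RADIUS = 2.40    # O6 atoms ring the axial cation channel
_C1_RADIUS = 7.00    # C1' anchors sit ~7 A out (adjacent C1'-C1' ~ 9.9 A)


def _template(flip: int) -> dict[str, np.ndarray]:
    """2D guanine footprint.  ``flip=1`` presents the opposite base face
    (the in-plane mirror image), which is how a syn guanosine in a down
    strand, or an anti guanosine in an up strand, sits in the tetrad."""
    atoms = {k: np.array(v, dtype=float) for k, v in _GUANINE_2D.items()}
    c8, n7, n9 = atoms["C8"], atoms["N7"], atoms["N9"]
    atoms["H8"] = c8 + 1.08 * unit(c8 - 0.5 * (n7 + n9))
    if not flip:
        atoms = {k: np.array([v[0], -v[1]]) for k, v in atoms.items()}
    return atoms


def _rot2(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s], [s, c]])


def _posed(template, theta, tx, ty):
    rot = _rot2(theta)
    return {k: rot @ v + np.array([tx, ty]) for k, v in template.items()}


@lru_cache(maxsize=4)
def _solve_pose(flip: int) -> dict[str, tuple[float, float]]:
    """In-plane pose of the slot-1 guanine of an ideal C4 tetrad.

    Slots are laid out clockwise viewed from the top (+z): slot k sits at
    the slot-1 pose rotated by -90(k-1) degrees.  A tetrad of unflipped
    bases (``flip=0``, the face an anti-G in a down strand shows the
    viewer) can only close its Hoogsteen donor->acceptor cycle (N1,N2 of
    the donor toward O6,N7 of the acceptor) in the clockwise direction; a
    tetrad of flipped bases (``flip=1``) closes it anticlockwise.  This
    sense/flip coupling is what makes the strand numbering rule gc-aware.
    Flipped bases are additionally pulled toward the unflipped C1'
    azimuth so that a stem mixing flipped and unflipped tetrads keeps a
    well-defined per-step twist.
    """
    template = _template(flip)
    sense = 1 if flip == 0 else -1  # geometric donation direction
    step = _rot2(-sense * 90.0)
    anchor_az = None
    if flip:
        ref = _solve_pose(0)
        c1 = ref["C1'"]
        anchor_az = math.atan2(c1[1], c1[0])

    def residuals(x):
        g0 = _posed(template, *x)
        g1 = {k: step @ v for k, v in g0.items()}
        res = [
            np.linalg.norm(g0["N1"] - g1["O6"]) - _HBOND_N1_O6,
            np.linalg.norm(g0["N2"] - g1["N7"]) - _HBOND_N2_N7,
            0.7 * (np.linalg.norm(g0["O6"]) - _O6_RADIUS),
            # sugars point outward: selects the physical branch of the fit
            0.3 * (np.linalg.norm(g0["C1'"]) - _C1_RADIUS),
        ]
        if anchor_az is not None:
            az = math.atan2(g0["C1'"][1], g0["C1'"][0])
            d = (az - anchor_az + math.pi) % (2 * math.pi) - math.pi
            res.append(30.0 * d)
        return res

    best = None
    for theta0 in range(0, 360, 45):
        for radius0 in (5.0, 7.0):
            for az0 in range(0, 360, 90):
                x0 = (theta0, radius0 * math.cos(math.radians(az0)),
                      radius0 * math.sin(math.radians(az0)))
                sol = least_squares(residuals, x0, method="lm", max_nfev=400)
                if best is None or sol.cost < best.cost:
                    best = sol
    pose = _posed(template, *best.x)
    d1 = np.linalg.norm(pose["N1"] - step @ pose["O6"])
    d2 = np.linalg.norm(pose["N2"] - step @ pose["N7"])
    if d1 > 3.4 or d2 > 3.5:
        raise RuntimeError(
            f"tetrad pose solve failed (flip={flip}): "
            f"H-bond distances {d1:.2f}/{d2:.2f} A"
        )
    return {k: (float(v[0]), float(v[1])) for k, v in pose.items()}


# ---------------------------------------------------------------------------
# Generator spec
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic G4.

    ``topology`` is a 4-letter d/u code (or topology name), optionally
    ``"code1/code2"`` for a two-block stem, in which case ``n_tetrads`` is a
    (block1, block2) pair.  ``gc_phase`` selects between the two
    complementary predominant gc patterns; ``gc_patterns`` overrides them
    explicitly (validated against the direction rule).  ``twist`` > 0 is
    right-handed.  ``noise`` is an isotropic coordinate jitter sigma in A.
    """

    topology: str = "dddd"
    n_tetrads: int | tuple[int, int] = 3
    twist: float = 28.0
    rise: float = 3.3
    radius: float = 10.68          # C5' radius; 15.1/sqrt(2), medium grooves
    gc_phase: int = 0
    gc_patterns: Sequence[str] | None = None
    loop_lengths: dict[str, int] | None = None
    bulge: tuple[int, int, int] | None = None      # (strand, after_tetrad, length)
    snapback: tuple[str, int] | None = None        # (kind, length); kind in 4 names
    reversed_first_guanine: bool = False
    with_hydrogens: bool = True
    c1_out_of_plane: tuple[int, int, float] | None = None  # (tetrad, slot, offset A)
    noise: float = 0.0
    seed: int = 0
    label: str = "SYN"

    @property
    def codes(self) -> list[str]:
        parts = [p.strip() for p in str(self.topology).split("/")]
        out = []
        for p in parts:
            code = CODE_BY_TOPOLOGY.get(p, p)
            if not (len(code) == 4 and set(code) <= {"d", "u"}):
                raise SpecValidationError(f"unknown topology {p!r}")
            block_topology_name(code)  # validates
            out.append(code)
        if out[0][0] != "d":
            raise SpecValidationError("strand 1 of the first block must be down")
        return out

    @property
    def block_sizes(self) -> list[int]:
        if isinstance(self.n_tetrads, (tuple, list)):
            sizes = list(self.n_tetrads)
        else:
            sizes = [int(self.n_tetrads)]
        if len(sizes) != len(self.codes):
            raise SpecValidationError("n_tetrads blocks do not match topology blocks")
        return sizes


@dataclass
class GroundTruth:
    """Every label the analysis pipeline is expected to recover."""

    topology_name: str
    topology_code: str
    directions: list[str]                 # per block, e.g. ["dddd"], ["dddd","uuuu"]
    gc_patterns: list[str]                # per tetrad, top -> bottom
    signature: str                        # direction-based groove letters
    handedness: str
    twist: float
    rise: float
    n_tetrads: int
    blocks: list[tuple[int, int]]         # 1-based inclusive tetrad ranges
    strand_positions: dict[int, list[int]]  # slot -> chain positions, top -> bottom
    gc_by_position: dict[int, str]
    loop_combination: str
    discontinuities: list[dict]
    anticlockwise: bool
    sequence_length: int


_SNAPBACK_KINDS = ("snapback_3bottom", "snapback_3top", "snapback_5bottom", "snapback_5top")


def signature_from_directions(code: str) -> str:
    """Groove letters from adjacent strand directions: up-down -> n,
    down-up -> w, same -> i (groove g lies between strands g and g+1)."""
    letters = []
    for g in range(4):
        a, b = code[g], code[(g + 1) % 4]
        if a == b:
            letters.append("i")
        elif (a, b) == ("u", "d"):
            letters.append("n")
        else:
            letters.append("w")
    return "".join(letters)


# ---------------------------------------------------------------------------
# Stem assembly
# ---------------------------------------------------------------------------

@dataclass
class _Guanosine:
    slot: int          # 1..4 (strand number in the generator's frame)
    tetrad: int        # 1..T, top to bottom
    gc: str            # 's' | 'a'
    micro_up: bool     # local chain direction at this guanosine
    position: int = 0  # chain position, assigned when the chain is threaded


def _cyl(radius: float, az_deg: float, z: float) -> np.ndarray:
    r = math.radians(az_deg)
    return np.array([radius * math.cos(r), radius * math.sin(r), z])


class _StemBuilder:
    """Geometry engine: turns a validated spec into atom coordinates."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        # reversed-first-guanine stems have every base in the opposite flip
        # state to the one its gc/direction implies (reversed-orientation pathology)
        self.flip_xor = 1 if spec.reversed_first_guanine else 0
        self.codes = spec.codes
        self.sizes = spec.block_sizes
        self.T = sum(self.sizes)
        if self.T < 2:
            raise SpecValidationError("a stem needs at least 2 tetrads")
        # tetrad -> (block index, code); tetrads are 1-based top to bottom
        self.block_of: dict[int, int] = {}
        t = 1
        self.blocks: list[tuple[int, int]] = []
        for b, size in enumerate(self.sizes):
            self.blocks.append((t, t + size - 1))
            for _ in range(size):
                self.block_of[t] = b
                t += 1
        self.z_top = (self.T - 1) * spec.rise

    def tetrad_z(self, t: int) -> float:
        return self.z_top - (t - 1) * self.spec.rise

    def tetrad_twist(self, t: int) -> float:
        return -(t - 1) * self.spec.twist  # math-convention; >0 twist is clockwise from top

    def direction_of(self, slot: int, tetrad: int) -> str:
        code = self.codes[self.block_of[tetrad]]
        return code[slot - 1]

    def base_atoms(self, g: _Guanosine, flip: int) -> dict[str, np.ndarray]:
        pose = _solve_pose(flip)
        rot = _rot2(-90.0 * (g.slot - 1) + self.tetrad_twist(g.tetrad))
        z = self.tetrad_z(g.tetrad)
        return {k: np.array([*(rot @ np.array(v)), z]) for k, v in pose.items()}

    def sugar_atoms(self, g: _Guanosine, base: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        spec = self.spec
        s = -1.0 if g.micro_up else 1.0       # +1: 5' side is up (down strand)
        chi = 60.0 if g.gc == "s" else 240.0
        c1 = base["C1'"]
        phi = math.degrees(math.atan2(c1[1], c1[0]))
        z = self.tetrad_z(g.tetrad)
        off = s
        atoms = {
            "C5'": _cyl(spec.radius, phi + off * 12.0, z + 1.2 * s),
            "P": _cyl(spec.radius + 0.39, phi + off * 17.0, z + 2.4 * s),
            "C3'": _cyl(spec.radius - 0.51, phi + off * 6.0, z - 1.2 * s),
        }
        atoms["O5'"] = atoms["C5'"] + 1.44 * unit(atoms["P"] - atoms["C5'"])
        atoms["O4'"] = place_atom(base["C4"], base["N9"], c1, 1.414, 108.2, chi)
        if spec.with_hydrogens:
            # D-chirality at C1': torsion(H1'-C1'-N9-C4) = chi + 120
            atoms["H1'"] = place_atom(base["C4"], base["N9"], c1, 1.09, 109.5, chi + 120.0)
        return atoms

    def guanosine_atoms(self, g: _Guanosine) -> dict[str, np.ndarray]:
        parity = int((g.gc == "s") ^ g.micro_up)
        atoms = self.base_atoms(g, parity ^ self.flip_xor)
        if not self.spec.with_hydrogens:
            atoms.pop("H8", None)
        atoms.update(self.sugar_atoms(g, atoms))
        pathology = self.spec.c1_out_of_plane
        if pathology and pathology[0] == g.tetrad and pathology[1] == g.slot:
            shift = np.array([0.0, 0.0, pathology[2]])
            for name in ("C1'", "O4'", "C3'", "C5'", "P", "O5'", "H1'"):
                if name in atoms:
                    atoms[name] = atoms[name] + shift
        return atoms

    def loop_atoms(self, start: np.ndarray, end: np.ndarray, n: int, lift: float) -> list[dict]:
        """Placeholder loop residues on an arc between two anchor points."""
        out = []
        r0 = np.linalg.norm(start[:2])
        r1 = np.linalg.norm(end[:2])
        a0 = math.atan2(start[1], start[0])
        a1 = math.atan2(end[1], end[0])
        da = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
        for i in range(1, n + 1):
            f = i / (n + 1)
            az = a0 + f * da
            radius = (1 - f) * r0 + f * r1 + 3.0 * math.sin(math.pi * f)
            z = (1 - f) * start[2] + f * end[2] + lift * math.sin(math.pi * f)
            c1 = np.array([radius * math.cos(az), radius * math.sin(az), z])
            out.append({"C1'": c1, "C5'": c1 + np.array([0.5, 0.5, 0.8]),
                        "P": c1 + np.array([-0.5, 0.8, 1.4])})
        return out


# ---------------------------------------------------------------------------
# Chain planning
# ---------------------------------------------------------------------------

def _plan_guanosines(spec: GeneratorSpec, builder: _StemBuilder) -> tuple[list[object], list[dict]]:
    """Return the chain plan (list of _Guanosine / loop markers) and the
    ground-truth discontinuity records."""
    codes, sizes = builder.codes, builder.sizes
    T = builder.T
    parities = _parities(spec, builder)
    gmap: dict[tuple[int, int], _Guanosine] = {}
    for t in range(1, T + 1):
        code = codes[builder.block_of[t]]
        for slot in range(1, 5):
            up = code[slot - 1] == "u"
            gc = "s" if (parities[t - 1] ^ up) else "a"
            gmap[(slot, t)] = _Guanosine(slot=slot, tetrad=t, gc=gc, micro_up=up)

    discontinuities: list[dict] = []
    plan: list[object] = []

    def strand_run(slot: int, tetrads: Iterable[int], code: str) -> list[_Guanosine]:
        ts = list(tetrads)
        if code[slot - 1] == "u":
            ts = ts[::-1]
        return [gmap[(slot, t)] for t in ts]

    loop_len = dict(_DEFAULT_LOOP_LEN)
    loop_len.update(spec.loop_lengths or {})

    if len(codes) == 1:
        code = codes[0]
        order = _VISIT_ORDER[code]
        runs = {slot: strand_run(slot, range(1, T + 1), code) for slot in order}
        snap_head, snap_tail = _apply_snapback(spec, builder, runs, order, gmap, discontinuities)
        if snap_head:
            plan.extend(snap_head)
            plan.append({"loop": max(2, loop_len["p"]), "snap": True})
        for i, slot in enumerate(order):
            run = runs[slot]
            for j, g in enumerate(run):
                plan.append(g)
                if spec.bulge and spec.bulge[0] == slot and j + 1 < len(run):
                    b_slot, after_t, b_len = spec.bulge
                    if run[j].tetrad == after_t:
                        plan.append({"loop": b_len, "bulge": True})
                        discontinuities.append(
                            {"kind": "bulge", "strand": b_slot,
                             "between_tetrads": (run[j].tetrad, run[j + 1].tetrad),
                             "length": b_len})
            if i + 1 < len(order):
                nxt = runs[order[i + 1]]
                kind = _loop_kind(run[-1], nxt[0])
                plan.append({"loop": loop_len[kind], "kind": kind})
        if snap_tail:
            plan.append({"loop": max(2, loop_len["p"]), "snap": True})
            plan.extend(snap_tail)
    else:
        t1_lo, t1_hi = builder.blocks[0]
        t2_lo, t2_hi = builder.blocks[1]
        order1 = _VISIT_ORDER[codes[0]]
        for i, slot in enumerate(order1):
            plan.extend(strand_run(slot, range(t1_lo, t1_hi + 1), codes[0]))
            if i + 1 < len(order1):
                plan.append({"loop": loop_len["p"]})
        plan.append({"loop": 4, "linker": True})
        order2 = tuple(reversed(order1))
        for i, slot in enumerate(order2):
            plan.extend(strand_run(slot, range(t2_lo, t2_hi + 1), codes[1]))
            if i + 1 < len(order2):
                plan.append({"loop": loop_len["p"]})
        for slot in range(1, 5):
            discontinuities.append(
                {"kind": "block_gap", "strand": slot, "between_tetrads": (t1_hi, t2_lo)})

    _validate_parity(gmap, builder)
    return plan, discontinuities


def _parities(spec: GeneratorSpec, builder: _StemBuilder) -> list[int]:
    T = builder.T
    if spec.gc_patterns is not None:
        if len(spec.gc_patterns) != T:
            raise SpecValidationError("gc_patterns must give one 4-letter string per tetrad")
        parities = []
        for t, pat in enumerate(spec.gc_patterns, start=1):
            code = builder.codes[builder.block_of[t]]
            p = None
            for slot in range(1, 5):
                up = code[slot - 1] == "u"
                # parity = syn XOR up: syn on a down strand (or anti on an
                # up strand) means the base is flipped relative to strand 1
                want = 1 if (pat[slot - 1] == "s") != up else 0
                if p is None:
                    p = want
                elif p != want:
                    raise SpecValidationError(
                        f"tetrad {t}: gc pattern {pat!r} is incompatible with strand "
                        f"directions {code!r} without a discontinuity (the syn/anti "
                        "orientation rule couples gc to strand direction)")
            parities.append(p)
        return parities
    # auto: canonical predominant pattern per block
    parities = []
    for b, (lo, hi) in enumerate(builder.blocks):
        parities.extend(_canonical_parities(builder.codes[b], hi - lo + 1, spec.gc_phase))
    return parities


def _validate_parity(gmap, builder) -> None:
    for t in range(1, builder.T + 1):
        ps = {(g.gc == "s") ^ g.micro_up for (slot, tt), g in gmap.items() if tt == t}
        if len(ps) > 1:
            raise SpecValidationError(
                f"tetrad {t}: mixed base-flip parity; gc pattern incompatible with "
                "micro-directions")


def _loop_kind(g_exit: _Guanosine, g_entry: _Guanosine) -> str:
    adjacent = (g_exit.slot - g_entry.slot) % 4 in (1, 3)
    if g_exit.tetrad == g_entry.tetrad:
        return "l" if adjacent else "d"
    return "p" if adjacent else "d"


def _loop_sign(g_exit: _Guanosine, g_entry: _Guanosine) -> str:
    """'+' when the chain hops anticlockwise (viewed from the top) between
    slots, i.e. clockwise when the stem is viewed bottom-to-top."""
    step = (g_entry.slot - g_exit.slot) % 4
    if step == 2:
        return ""  # diagonal: no progression sign
    return "+" if step == 3 else "-"


def _apply_snapback(spec, builder, runs, order, gmap, discontinuities):
    """Pull guanosines out of their strand run to the chain 5'/3' extremity."""
    if spec.snapback is None:
        return [], []
    kind, length = spec.snapback
    if kind not in _SNAPBACK_KINDS:
        raise SpecValidationError(f"snapback kind must be one of {_SNAPBACK_KINDS}")
    if length not in (1, 2):
        raise SpecValidationError("snapback length must be 1 or 2")
    three_prime = kind.startswith("snapback_3")
    bottom = kind.endswith("bottom")
    slot = order[-1] if three_prime else order[0]
    run = runs[slot]
    # the snapback guanosines occupy the first (top) / last (bottom) tetrads
    want_ts = (
        set(range(builder.T - length + 1, builder.T + 1)) if bottom
        else set(range(1, length + 1))
    )
    take = sorted((g for g in run if g.tetrad in want_ts), key=lambda g: g.tetrad)
    if len(take) != length:
        raise SpecValidationError(f"{kind}: strand {slot} does not span the target tetrads")
    runs[slot] = [g for g in run if g not in take]
    if not runs[slot]:
        raise SpecValidationError("snapback would consume the whole strand")
    if length == 1:
        g = take[0]
        g.micro_up = not g.micro_up          # a 1-nt snapback is reversed
        g.gc = "s" if g.gc == "a" else "a"   # which flips its gc
    discontinuities.append({"kind": kind, "strand": slot, "length": length,
                            "tetrad": builder.T if bottom else 1})
    # chain order: 3'-bottom continues downward (..., T-1, T); 3'-top climbs
    # (..., 2, 1); 5'-bottom starts upward (T, T-1, ...); 5'-top starts (1, 2, ...)
    if three_prime:
        return [], (take if bottom else take[::-1])
    return (take[::-1] if bottom else take), []


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def build_stem(spec: GeneratorSpec) -> tuple[StructureModel, GroundTruth]:
    """Build one synthetic G4 and its ground truth."""
    builder = _StemBuilder(spec)
    plan, discontinuities = _plan_guanosines(spec, builder)
    rng = np.random.default_rng(spec.seed)

    residues: list[Residue] = []
    position = 0
    prev_anchor: np.ndarray | None = None
    pending_loops: list[tuple[int, int]] = []  # (index in residues, length) for placement
    chain_guanosines: list[_Guanosine] = []

    # First pass: assign chain positions and create guanosine residues.
    items: list[tuple[str, object]] = []
    for entry in plan:
        if isinstance(entry, _Guanosine):
            items.append(("g", entry))
        else:
            items.append(("loop", entry))

    loop_sites: list[tuple[int, int]] = []
    for kind, entry in items:
        if kind == "g":
            position += 1
            entry.position = position
            atoms = builder.guanosine_atoms(entry)
            residues.append(Residue(name="DG", chain_id="A", position=position, atoms=atoms))
            chain_guanosines.append(entry)
        else:
            n = int(entry["loop"])
            loop_sites.append((len(residues), n))
            for _ in range(n):
                position += 1
                residues.append(Residue(name="DT", chain_id="A", position=position, atoms={}))

    # Second pass: place loop residues between their flanking anchors.
    for index, n in loop_sites:
        if n == 0:
            continue
        before = next((r for r in reversed(residues[:index]) if r.name == "DG"), None)
        after = next((r for r in residues[index + n:] if r.name == "DG"), None)
        start = before.atoms["C3'"] if before is not None else np.array([14.0, 0.0, builder.z_top + 4])
        end = after.atoms["C5'"] if after is not None else np.array([14.0, 0.0, -4.0])
        lift = 3.0 if abs(start[2] - end[2]) < builder.spec.rise else 0.0
        for res, atoms in zip(residues[index:index + n], builder.loop_atoms(start, end, n, lift)):
            res.atoms.update(atoms)

    if spec.noise > 0:
        for res in residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(0.0, spec.noise, 3)

    model = StructureModel(
        structure_id=spec.label,
        chain_id="A",
        residues=residues,
        experiment_kind=ExperimentKind.synthetic,
    )

    truth = _ground_truth(spec, builder, plan, discontinuities, position)
    return model, truth


def _ground_truth(spec, builder, plan, discontinuities, seq_len) -> GroundTruth:
    guanosines = [e for e in plan if isinstance(e, _Guanosine)]
    strand_positions: dict[int, list[int]] = {}
    for slot in range(1, 5):
        members = sorted((g for g in guanosines if g.slot == slot), key=lambda g: g.tetrad)
        strand_positions[slot] = [g.position for g in members]
    patterns = []
    for t in range(1, builder.T + 1):
        by_slot = {g.slot: g for g in guanosines if g.tetrad == t}
        patterns.append("".join(by_slot[s].gc for s in range(1, 5)))
    # loop combination (basic loops only, chain order)
    combo = []
    stem_in_chain = sorted(guanosines, key=lambda g: g.position)
    for a, b in zip(stem_in_chain, stem_in_chain[1:]):
        if a.slot == b.slot:
            continue  # continuation, bulge or linker inside a strand column
        kind = _loop_kind(a, b)
        if kind == "p" and b.position - a.position == 1:
            kind = "v"  # 0-nt propeller: V-shaped loop
        combo.append(_loop_sign(a, b) + kind)
    code = builder.codes[0]
    name = block_topology_name(code)
    if len(builder.codes) > 1:
        name = " / ".join(block_topology_name(c) for c in builder.codes)
    return GroundTruth(
        topology_name=name,
        topology_code="/".join(builder.codes),
        directions=list(builder.codes),
        gc_patterns=patterns,
        signature=signature_from_directions(code),
        handedness="right" if spec.twist > 0 else "left",
        twist=spec.twist,
        rise=spec.rise,
        n_tetrads=builder.T,
        blocks=list(builder.blocks),
        strand_positions=strand_positions,
        gc_by_position={g.position: g.gc for g in guanosines},
        loop_combination="".join(combo),
        discontinuities=discontinuities,
        anticlockwise=spec.reversed_first_guanine,
        sequence_length=seq_len,
    )


def build_cohort(
    specs: Sequence[GeneratorSpec],
    out_dir: str | Path,
    seed: int = 0,
) -> "pd.DataFrame":
    """Write one PDB per spec plus a ground-truth TSV; returns the truth table."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        spec.seed = int((seed * 100003 + i * 7919) % (2**31 - 1))
        if spec.label == "SYN":
            spec.label = f"SYN{i:03d}"
        model, truth = build_stem(spec)
        path = out_dir / f"{spec.label}.pdb"
        write_pdb(model, path)
        rows.append({
            "label": spec.label,
            "file": path.name,
            "topology": truth.topology_name,
            "code": truth.topology_code,
            "n_tetrads": truth.n_tetrads,
            "twist": truth.twist,
            "signature": truth.signature,
            "handedness": truth.handedness,
            "gc_patterns": ";".join(truth.gc_patterns),
            "loops": truth.loop_combination,
            "blocks": ";".join(f"{a}-{b}" for a, b in truth.blocks),
            "block_gap": any(d["kind"] == "block_gap" for d in truth.discontinuities),
            "n_residues": truth.sequence_length,
        })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return table
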