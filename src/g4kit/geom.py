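"""Groove widths, minimum groove distances, Psi, twist and tilt.

Groove g is the channel between strands g and g+1 (groove 4 closes the
ring between strands 4 and 1).  Its per-tetrad distance is measured
between like atoms (C5', C3' or P) of the two delimiting guanosines of
the same tetrad; the groove width is the mean over tetrads, and the
perimeter is the sum of the four widths.  Because tilted strands bring
guanosines of *different* tetrads closer together, the minimum groove
distance (searched over the neighbouring tetrad layers) is the better
estimate of the space a lateral ligand sees; the top tetrad is skipped
because its minimum is mostly the same-tetrad distance.

The relative orientation of two stacking guanines i, j is the
pseudo-dihedral Psi = N1(i)-N9(i)-N9(j)-N1(j), read along the chain
direction of the strand (order reversal leaves the dihedral unchanged, so
only the succession label, not Psi, depends on the reading direction).

Per-step twist is the rotation of the strand anchor (C1') about the local
stem axis, signed so that right-handed (clockwise viewed from the top,
going down) is positive; tilt is the inclination of the C1'(i) -> C1'(j)
step to the axis.  Both are read along the chain.  For anticlockwise-
numbered stems the reported tilt is the supplement whenever the step
twist disagrees in sign with the numbering sense -- this reproduces the
pseudo-average diagnostic: regular stems keep (twist + tilt) / 2 near 40
degrees, stems with a reversed first stem-guanine leave the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import config
from ._linalg import dihedral, signed_angle, unit
from .glyco import GcRecord
from .io import Residue
from .stem import Stem, Strand

__all__ = [
    "GrooveProfile",
    "StackStep",
    "HandednessCall",
    "groove_distances",
    "groove_widths",
    "minimum_groove_distances",
    "psi_angle",
    "twist_tilt",
    "handedness",
    "reversed_first_guanine_check",
    "direction_signature",
    "threshold_signature",
]


@dataclass
class GrooveProfile:
    """Per-groove distances and widths for one atom kind."""

    atom_kind: str                                  # "C5'" | "C3'" | "P"
    per_tetrad: np.ndarray                          # shape (4, T); NaN = missing atom
    width: list[float] = field(default_factory=list)        # mean per groove
    width_sd: list[float] = field(default_factory=list)
    min_distance: dict[int, list[float]] = field(default_factory=dict)  # groove -> per tetrad 2..T
    perimeter: float = float("nan")
    signature: str = ""                             # direction-based letters
    signature_threshold: str = ""                   # width-threshold letters

    @property
    def n_tetrads(self) -> int:
        return self.per_tetrad.shape[1]


@dataclass
class StackStep:
    """One stacking guanine pair along a strand (read in chain order)."""

    strand: int
    tetrads: tuple[int, int]        # chain order
    positions: tuple[int, int]      # chain positions of the two guanosines
    succession: str                 # 'aa' | 'as' | 'sa' | 'ss' (chain order)
    psi: float
    twist: float
    tilt: float
    block: int = 0

    @property
    def pseudo_average(self) -> float:
        return 0.5 * (self.twist + self.tilt)


@dataclass
class HandednessCall:
    value: str                      # right | left | mixed
    per_step_signs: list[int]


# ---------------------------------------------------------------------------
# Grooves
# ---------------------------------------------------------------------------

def groove_distances(stem: Stem, atom_kind: str = "C5'") -> GrooveProfile:
    """Per-tetrad distances of the four grooves (NaN where atoms missing)."""
    T = stem.n_tetrads
    d = np.full((4, T), np.nan)
    for g in range(4):
        s_a = stem.strands[g]
        s_b = stem.strands[(g + 1) % 4]
        for t in range(T):
            ra, rb = s_a.guanosines[t], s_b.guanosines[t]
            if ra.has(atom_kind) and rb.has(atom_kind):
                d[g, t] = np.linalg.norm(ra.coord(atom_kind) - rb.coord(atom_kind))
    return GrooveProfile(atom_kind=atom_kind, per_tetrad=d)


def direction_signature(stem: Stem) -> str:
    """Groove letters from adjacent strand directions: up-down -> n
    (narrow), down-up -> w (wide), same direction -> i (intermediate)."""
    letters = []
    for g in range(4):
        a = stem.strands[g].direction
        b = stem.strands[(g + 1) % 4].direction
        if "undetermined" in (a, b):
            letters.append("?")
        elif a == b:
            letters.append("i")
        elif (a, b) == ("up", "down"):
            letters.append("n")
        else:
            letters.append("w")
    return "".join(letters)


def threshold_signature(widths: list[float]) -> str:
    """Letters from the width values themselves, class boundaries at the
    midpoints between the cohort class means (C5' calibration)."""
    out = []
    for w in widths:
        if math.isnan(w):
            out.append("?")
        elif w < config.GROOVE_N_I_BOUNDARY:
            out.append("n")
        elif w < config.GROOVE_I_W_BOUNDARY:
            out.append("i")
        else:
            out.append("w")
    return "".join(out)


def groove_widths(stem: Stem, profile: GrooveProfile) -> GrooveProfile:
    """Fill widths, SDs, perimeter and both signatures on a profile."""
    with np.errstate(all="ignore"):
        profile.width = [float(np.nanmean(row)) if not np.all(np.isnan(row)) else float("nan")
                         for row in profile.per_tetrad]
        profile.width_sd = [float(np.nanstd(row)) if not np.all(np.isnan(row)) else float("nan")
                            for row in profile.per_tetrad]
    profile.perimeter = float(np.sum(profile.width))
    profile.signature = direction_signature(stem)
    profile.signature_threshold = threshold_signature(profile.width)
    return profile


def minimum_groove_distances(
    stem: Stem,
    atom_kind: str = "C3'",
    window: int = 1,
) -> dict[int, list[float]]:
    """Minimum atom-atom distance per groove for tetrads 2..T.

    For tetrad t the search pairs the guanosine of one delimiting strand in
    tetrad t with the guanosines of the other strand in tetrads t-window ..
    t+window (both roles), because tilt brings cross-tetrad pairs closer
    than the same-tetrad pair.  Tetrad 1 is skipped: its minimum is mostly
    the same-tetrad distance.
    """
    T = stem.n_tetrads
    out: dict[int, list[float]] = {}
    for g in range(4):
        s_a = stem.strands[g]
        s_b = stem.strands[(g + 1) % 4]
        per_tetrad = []
        for t in range(2, T + 1):
            best = np.inf
            lo, hi = max(1, t - window), min(T, t + window)
            for one, other in ((s_a, s_b), (s_b, s_a)):
                r1 = one.guanosines[t - 1]
                if not r1.has(atom_kind):
                    continue
                for tt in range(lo, hi + 1):
                    r2 = other.guanosines[tt - 1]
                    if r2.has(atom_kind):
                        best = min(best, float(np.linalg.norm(
                            r1.coord(atom_kind) - r2.coord(atom_kind))))
            per_tetrad.append(best if np.isfinite(best) else float("nan"))
        out[g + 1] = per_tetrad
    return out


# ---------------------------------------------------------------------------
# Psi, twist, tilt
# ---------------------------------------------------------------------------

def psi_angle(g_i: Residue, g_j: Residue) -> float:
    """Pseudo-dihedral N1(i)-N9(i)-N9(j)-N1(j), degrees in (-180, 180].

    The ordered pair follows the chain direction; note the dihedral is
    invariant under full order reversal, so the value does not depend on
    which way the pair is read -- only the succession label does.
    """
    return dihedral(g_i.coord("N1"), g_i.coord("N9"),
                    g_j.coord("N9"), g_j.coord("N1"))


def _letter(records: dict, residue: Residue) -> str:
    rec = records.get(residue.key)
    return rec.letter if rec is not None else "?"


def twist_tilt(
    stem: Stem,
    gc_records: dict[tuple, GcRecord] | None = None,
    reference_atom: str = config.TWIST_REFERENCE_ATOM,
) -> list[StackStep]:
    """Per-strand, per-adjacent-tetrad-pair stack steps within each block."""
    gc_records = gc_records or {}
    steps: list[StackStep] = []
    cycle_sign = -1 if stem.anticlockwise else 1
    for block_index, (lo, hi) in enumerate(stem.blocks):
        if hi - lo < 1:
            continue
        for strand in stem.strands:
            for t in range(lo, hi):
                g_top, g_bot = strand.guanosines[t - 1], strand.guanosines[t]
                if not (g_top.has(reference_atom) and g_bot.has(reference_atom)):
                    continue
                c_top = stem.tetrads[t - 1].centroid
                c_bot = stem.tetrads[t].centroid
                axis = c_bot - c_top          # local top -> bottom
                if np.linalg.norm(axis) < 1e-6:
                    raise ValueError("degenerate stem axis (coincident tetrad centroids)")
                axis = unit(axis)
                rank_top = stem.model.chain_rank(g_top)
                rank_bot = stem.model.chain_rank(g_bot)
                if rank_top <= rank_bot:      # chain runs downwards here
                    g_a, g_b = g_top, g_bot
                    c_a, c_b = c_top, c_bot
                    s = 1.0
                else:
                    g_a, g_b = g_bot, g_top
                    c_a, c_b = c_bot, c_top
                    s = -1.0
                v_a = g_a.coord(reference_atom) - c_a
                v_b = g_b.coord(reference_atom) - c_b
                twist = signed_angle(v_a, v_b, s * axis)
                step_vec = g_b.coord(reference_atom) - g_a.coord(reference_atom)
                cosang = np.clip(np.dot(unit(step_vec), s * axis), -1.0, 1.0)
                tilt = math.degrees(math.acos(cosang))
                if tilt > 90.0:
                    tilt = 180.0 - tilt       # raw tilt to the (unsigned) axis
                if np.sign(twist) * cycle_sign < 0:
                    tilt = 180.0 - tilt       # numbering-sense mismatch: supplement
                succession = _letter(gc_records, g_a) + _letter(gc_records, g_b)
                steps.append(StackStep(
                    strand=strand.number,
                    tetrads=(t, t + 1) if s > 0 else (t + 1, t),
                    positions=(g_a.position, g_b.position),
                    succession=succession,
                    psi=psi_angle(g_a, g_b),
                    twist=float(twist),
                    tilt=float(tilt),
                    block=block_index,
                ))
    return steps


def handedness(steps: list[StackStep]) -> HandednessCall:
    """right iff every step twist > 0, left iff all < 0, else mixed."""
    if not steps:
        raise ValueError("no stack steps")
    signs = [int(np.sign(s.twist)) for s in steps]
    if all(s > 0 for s in signs):
        value = "right"
    elif all(s < 0 for s in signs):
        value = "left"
    else:
        value = "mixed"
    return HandednessCall(value=value, per_step_signs=signs)


def reversed_first_guanine_check(
    steps: list[StackStep],
    band: tuple[float, float] = config.PSEUDO_AVERAGE_BAND,
) -> bool:
    """True when the mean pseudo-average of twist and tilt leaves the
    regular ~40 degree band -- the cheap flag for a reversed first
    stem-guanine (above the band) or a reversed-numbering left-handed stem
    (below it)."""
    if not steps:
        raise ValueError("no stack steps")
    mean_pa = float(np.mean([s.pseudo_average for s in steps]))
    lo, hi = band
    return not (lo <= mean_pa <= hi)
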