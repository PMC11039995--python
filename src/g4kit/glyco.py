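"""Glycosidic torsion chi and the syn/anti classification.

The glycosidic configuration (gc) of a guanosine is read from the torsion
chi = O4'-C1'-N9-C4, mapped to (0, 360] so that the published intervals
apply verbatim: syn for chi in (0, 140], anti for chi in (152, 300].  The
two gaps, (140, 152] and (300, 360], are indeterminacy regions where the
call falls back to interatomic distances: d(H1', H8) when hydrogens are
present (short for syn -- the classic syn NOE contact), otherwise
d(N3, O5') (the syn conformation brings O5' over the base, close to N3).
The decision boundaries are calibrated on guanosines generated at
unambiguous chi; see ``g4kit.config``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import config
from ._linalg import dihedral
from .io import Residue

__all__ = ["GcCall", "GcRule", "GcRecord", "chi_torsion", "classify_gc"]


class GcCall(str, Enum):
    syn = "syn"
    anti = "anti"
    undetermined = "undetermined"

    @property
    def letter(self) -> str:
        return {"syn": "s", "anti": "a", "undetermined": "?"}[self.value]


class GcRule(str, Enum):
    interval = "interval"
    h1p_h8 = "h1p_h8"
    n3_o5p = "n3_o5p"
    none = "none"


@dataclass(frozen=True)
class GcRecord:
    """Per-guanosine chi and syn/anti call, with the rule that decided it."""

    residue_key: tuple[str, int, str]
    chi: float | None
    call: GcCall
    rule: GcRule

    @property
    def letter(self) -> str:
        return self.call.letter


def chi_torsion(residue: Residue, atoms: tuple[str, str, str, str] = config.CHI_ATOMS) -> float:
    """chi in (0, 360]; raises KeyError when a defining atom is absent."""
    coords = [residue.coord(a) for a in atoms]
    ang = dihedral(*coords) % 360.0
    return 360.0 if ang == 0.0 else float(ang)


def _interval_call(chi: float) -> GcCall | None:
    lo, hi = config.CHI_SYN_INTERVAL
    if lo < chi <= hi:
        return GcCall.syn
    lo, hi = config.CHI_ANTI_INTERVAL
    if lo < chi <= hi:
        return GcCall.anti
    return None


def classify_gc(residue: Residue) -> GcRecord:
    """Classify a guanosine as syn/anti.

    Interval rule on chi first; in the indeterminacy regions the distance
    fallbacks decide; with no usable atoms the record is undetermined
    (undetermined is a value, not an error).
    """
    try:
        chi = chi_torsion(residue)
    except KeyError:
        return GcRecord(residue.key, None, GcCall.undetermined, GcRule.none)

    call = _interval_call(chi)
    if call is not None:
        return GcRecord(residue.key, chi, call, GcRule.interval)

    if residue.has("H1'", "H8"):
        d = float(np.linalg.norm(residue.coord("H1'") - residue.coord("H8")))
        call = GcCall.syn if d < config.H1P_H8_SYN_BELOW else GcCall.anti
        return GcRecord(residue.key, chi, call, GcRule.h1p_h8)
    if residue.has("N3", "O5'"):
        d = float(np.linalg.norm(residue.coord("N3") - residue.coord("O5'")))
        call = GcCall.syn if d < config.N3_O5P_SYN_BELOW else GcCall.anti
        return GcRecord(residue.key, chi, call, GcRule.n3_o5p)
    return GcRecord(residue.key, chi, GcCall.undetermined, GcRule.none)
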