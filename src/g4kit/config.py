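"""Tunable parameters of the G-quadruplex analysis, with their defaults.

Every geometric cutoff that the method needs but that is not a published
constant lives here, so a user can tighten or relax the detection without
touching the algorithms.  Published constants (the chi intervals, the
groove-width class means) are also collected here for reference from one
place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Glycosidic configuration
# ---------------------------------------------------------------------------

#: chi in (0, 140] degrees -> syn; chi in (152, 300] -> anti.  The two gaps,
#: (140, 152] and (300, 360], are indeterminacy regions resolved by distance
#: fallbacks.
CHI_SYN_INTERVAL = (0.0, 140.0)
CHI_ANTI_INTERVAL = (152.0, 300.0)

#: Atom quadruplet of the purine chi torsion (IUPAC convention).
CHI_ATOMS = ("O4'", "C1'", "N9", "C4")

#: Distance fallbacks for chi in the indeterminacy regions.  The thresholds
#: were calibrated on synthetic guanosines built at unambiguous chi (60 deg
#: syn, 240 deg anti), which give d(H1', H8) = 2.58 A (syn, the classic
#: short syn NOE contact) vs 3.92 A (anti) and d(N3, O5') = 5.59 A (syn,
#: O5' over the base) vs 7.29 A (anti); the boundaries sit at the midpoints.
H1P_H8_SYN_BELOW = 3.25   # Angstrom; d(H1', H8) < threshold -> syn
N3_O5P_SYN_BELOW = 6.44   # Angstrom; d(N3, O5') < threshold -> syn


# ---------------------------------------------------------------------------
# Tetrad detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HbondParams:
    """Hoogsteen hydrogen-bond geometry cutoffs (heavy-atom distances).

    A donor guanine's Watson-Crick edge (N1, N2) donates to the acceptor's
    Hoogsteen edge (O6, N7).  Both contacts within cutoff is preferred; a
    single contact is accepted when ``require_both`` is False.
    """

    n1_o6_max: float = 3.5
    n2_n7_max: float = 3.6
    require_both: bool = False
    #: inter-tetrad stacking adjacency: centroid distance and normal alignment
    stack_centroid_max: float = 5.5
    stack_normal_min_cos: float = 0.7
    #: C1' out-of-base-plane distance that marks a degenerate guanosine
    planarity_tol: float = 0.9


# ---------------------------------------------------------------------------
# Groove widths
# ---------------------------------------------------------------------------

#: Cohort class means of the C5'-C5' groove widths (Angstrom): narrow,
#: medium (intermediate), wide.
GROOVE_CLASS_MEANS = {"n": 11.4, "i": 15.1, "w": 17.3}

#: Threshold-based signature boundaries: midpoints between the class means.
GROOVE_N_I_BOUNDARY = 0.5 * (GROOVE_CLASS_MEANS["n"] + GROOVE_CLASS_MEANS["i"])
GROOVE_I_W_BOUNDARY = 0.5 * (GROOVE_CLASS_MEANS["i"] + GROOVE_CLASS_MEANS["w"])

#: Histogram bin widths used by the cohort layer.
GROOVE_HIST_BIN = 0.1  # Angstrom
PSI_HIST_BIN = 1.0     # degrees


# ---------------------------------------------------------------------------
# Twist / tilt
# ---------------------------------------------------------------------------

#: Reference atom for the per-step twist and tilt (the base anchor).
TWIST_REFERENCE_ATOM = "C1'"

#: Regular stems keep the pseudo-average of twist and tilt near 40 degrees;
#: outside this band the first stem-guanine is suspected reversed.
PSEUDO_AVERAGE_BAND = (25.0, 55.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of all knobs used by the per-structure pipeline."""

    hbond: HbondParams = field(default_factory=HbondParams)
    chi_atoms: tuple[str, str, str, str] = CHI_ATOMS
    groove_atom: str = "C5'"
    min_distance_atom: str = "C3'"
    pseudo_average_band: tuple[float, float] = PSEUDO_AVERAGE_BAND
    #: search window (in tetrads) for the minimum groove distance
    min_distance_window: int = 1
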