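"""Groove widths, minimum distances, Psi, twist/tilt, handedness."""

import math

import numpy as np
import pytest

from conftest import rigid_transform
from g4kit import GeneratorSpec
from g4kit import geom
from g4kit.glyco import classify_gc
from g4kit.io import is_guanine
from g4kit.stem import build_stem_from_model
from g4kit.synthgen import build_stem


def stem_and_steps(**kw):
    model, truth = build_stem(GeneratorSpec(**kw))
    stem = build_stem_from_model(model)
    recs = {r.key: classify_gc(r) for r in model.residues if is_guanine(r)}
    return model, truth, stem, geom.twist_tilt(stem, recs)


def test_c4_symmetric_parallel_grooves_equal_and_perimeter_exact():
    """In a C4-symmetric parallel stem all per-tetrad groove distances are
    equal and the perimeter equals the sum of the four widths exactly."""
    _, _, stem, _ = stem_and_steps(topology="dddd", n_tetrads=3)
    prof = geom.groove_widths(stem, geom.groove_distances(stem, "C5'"))
    assert np.allclose(prof.per_tetrad, prof.per_tetrad[0, 0], atol=1e-6)
    assert prof.perimeter == pytest.approx(sum(prof.width), abs=0.0)
    assert prof.signature == "iiii" and prof.signature_threshold == "iiii"


def test_antiparallel_chair_alternates_wide_narrow():
    """A chair stem alternates wide/narrow grooves; the letters match the
    generator geometry (down-up wide, up-down narrow)."""
    _, _, stem, _ = stem_and_steps(topology="dudu", n_tetrads=3)
    prof = geom.groove_widths(stem, geom.groove_distances(stem, "C5'"))
    assert prof.signature == "wnwn"
    assert prof.width[0] > prof.width[1]
    assert prof.width[0] == pytest.approx(prof.width[2], abs=1e-6)


def test_missing_atom_entry_is_nan_and_excluded_from_mean():
    model, truth, stem, _ = stem_and_steps(topology="dddd", n_tetrads=3)
    victim = stem.strands[0].guanosines[1]
    del victim.atoms["C5'"]
    prof = geom.groove_widths(stem, geom.groove_distances(stem, "C5'"))
    assert np.isnan(prof.per_tetrad[0, 1]) and np.isnan(prof.per_tetrad[3, 1])
    assert np.isfinite(prof.width[0])  # mean over the remaining tetrads


def test_minimum_distance_untwisted_equals_same_tetrad():
    """With zero twist there is no stagger: the cross-tetrad search cannot
    beat the same-tetrad distance."""
    _, _, stem, _ = stem_and_steps(topology="dddd", n_tetrads=3, twist=0.0)
    prof = geom.groove_distances(stem, "C3'")
    mins = geom.minimum_groove_distances(stem, "C3'")
    for g in range(1, 5):
        for t in (2, 3):
            assert mins[g][t - 2] == pytest.approx(prof.per_tetrad[g - 1, t - 1], abs=1e-6)


def test_minimum_distance_shrinks_with_twist_monotonically():
    """Brute-force oracle: more twist (hence tilt) strictly shrinks the
    minimum groove distance while the same-tetrad distance is fixed."""
    minima = []
    for tau in (5.0, 15.0, 25.0, 35.0):
        _, _, stem, _ = stem_and_steps(topology="dddd", n_tetrads=3, twist=tau)
        # independent brute force over the groove's atom pairs within the
        # adjacent-tetrad search window the method defines
        s1, s2 = stem.strands[0], stem.strands[1]
        brute = min(
            np.linalg.norm(a.coord("C3'") - b.coord("C3'"))
            for ta, a in enumerate(s1.guanosines)
            for tb, b in enumerate(s2.guanosines)
            if abs(ta - tb) <= 1 and max(ta, tb) >= 1)
        mins = geom.minimum_groove_distances(stem, "C3'")
        assert min(mins[1]) == pytest.approx(brute, abs=1e-6)
        minima.append(min(mins[1]))
    assert all(a > b for a, b in zip(minima, minima[1:]))


def test_psi_order_reversal_identity_on_random_stacks():
    """psi(j, i) == psi(i, j): the dihedral is invariant under full order
    reversal, so only the succession label depends on reading direction."""
    from g4kit.io import Residue

    rng = np.random.default_rng(42)
    for _ in range(1000):
        a = Residue("DG", "A", 1, atoms={"N1": rng.normal(size=3) * 5,
                                         "N9": rng.normal(size=3) * 5})
        b = Residue("DG", "A", 2, atoms={"N1": rng.normal(size=3) * 5,
                                         "N9": rng.normal(size=3) * 5})
        p1 = geom.psi_angle(a, b)
        p2 = geom.psi_angle(b, a)
        assert p1 == pytest.approx(p2, abs=1e-9)


def test_psi_rigid_invariance_and_mirror_sign_flip():
    model, truth, stem, steps = stem_and_steps(topology="dudu", n_tetrads=3)
    ref = [s.psi for s in steps]
    moved = rigid_transform(model, np.random.default_rng(3))
    m_stem = build_stem_from_model(moved)
    recs = {r.key: classify_gc(r) for r in moved.residues if is_guanine(r)}
    got = [s.psi for s in geom.twist_tilt(m_stem, recs)]
    assert np.allclose(sorted(ref), sorted(got), atol=1e-6)

    mirrored = rigid_transform(model, np.random.default_rng(4), mirror=True)
    flipped = []
    for res in mirrored.residues:
        if res.name != "DG":
            continue
    # compare psi of the same residue pairs directly (mirroring breaks chi,
    # so the full pipeline is not rerun here)
    res_m = {r.position: r for r in mirrored.residues}
    res_o = {r.position: r for r in model.residues}
    for s in steps:
        a, b = s.positions
        assert geom.psi_angle(res_m[a], res_m[b]) == pytest.approx(
            -geom.psi_angle(res_o[a], res_o[b]), abs=1e-6)


def test_translated_copy_gives_zero_psi():
    """A guanine stacked as an exact translate of another has parallel
    N1-N9 vectors: Psi = 0."""
    import copy
    model, *_ = stem_and_steps(topology="dddd", n_tetrads=2)
    g = next(r for r in model.residues if r.name == "DG")
    h = copy.deepcopy(g)
    for a in h.atoms:
        h.atoms[a] = h.atoms[a] + np.array([0.0, 0.0, 3.3])
    assert geom.psi_angle(g, h) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("tau", [-40.0, -20.0, -5.0, 5.0, 17.0, 28.0, 34.0, 40.0])
def test_twist_recovery_within_one_degree(tau):
    for code in ("dddd", "dudu"):
        _, _, _, steps = stem_and_steps(topology=code, n_tetrads=3, twist=tau)
        assert max(abs(s.twist - tau) for s in steps) <= 1.0


def test_tilt_closed_form_on_the_generated_helix():
    """tilt = atan2(lateral chord, rise), with the chord given by the C1'
    radius and the per-step twist (closed form on a mathematical helix)."""
    model, truth, stem, steps = stem_and_steps(topology="dddd", n_tetrads=3, twist=28.0)
    c1 = stem.strands[0].guanosines[0].coord("C1'")
    centroid = stem.tetrads[0].centroid
    radius = np.linalg.norm((c1 - centroid)[:2]) if abs(stem.axis_topdown[2]) > 0.99 \
        else np.linalg.norm(np.cross(c1 - centroid, stem.axis_topdown))
    chord = 2.0 * radius * math.sin(math.radians(28.0 / 2))
    expected = math.degrees(math.atan2(chord, truth.rise))
    for s in steps:
        assert s.tilt == pytest.approx(expected, abs=0.5)


def test_handedness_calls():
    _, _, _, right = stem_and_steps(topology="dddd", n_tetrads=3, twist=28.0)
    _, _, _, left = stem_and_steps(topology="dddd", n_tetrads=3, twist=-20.0)
    assert geom.handedness(right).value == "right"
    assert geom.handedness(left).value == "left"
    mixed = right[:2] + left[:2]
    assert geom.handedness(mixed).value == "mixed"


def test_pseudo_average_band_diagnostic():
    """Regular stems sit inside the 25-55 degree pseudo-average band;
    stems built with a reversed first stem-guanine leave it (above for
    right-handed, below for left-handed)."""
    _, _, _, steps = stem_and_steps(topology="dddd", n_tetrads=3, twist=28.0)
    assert not geom.reversed_first_guanine_check(steps)
    _, _, stem, steps = stem_and_steps(topology="dddd", n_tetrads=3, twist=28.0,
                                       reversed_first_guanine=True)
    assert stem.anticlockwise
    assert np.mean([s.pseudo_average for s in steps]) > 55.0
    assert geom.reversed_first_guanine_check(steps)
    _, _, _, steps = stem_and_steps(topology="dddd", n_tetrads=3, twist=-20.0,
                                    reversed_first_guanine=True)
    assert np.mean([s.pseudo_average for s in steps]) < 25.0
    assert geom.reversed_first_guanine_check(steps)
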