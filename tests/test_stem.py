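"""Tetrad detection, strand assembly and discontinuities."""

import numpy as np
import pytest

from conftest import ALL_CODES, rigid_transform
from g4kit import GeneratorSpec
from g4kit._linalg import fit_plane
from g4kit.io import GUANINE_BASE_ATOMS, Residue, StructureModel, ExperimentKind
from g4kit.stem import (
    NotAG4Error,
    build_stem_from_model,
    detect_discontinuities,
    detect_tetrads,
    micro_directions,
)
from g4kit.synthgen import build_stem


def dirs_of(stem):
    return "".join({"down": "d", "up": "u", "undetermined": "?"}[s.direction]
                   for s in stem.strands)


def test_ideal_parallel_stem_detection():
    """3 clean tetrads, all planar, ordered and numbered as generated."""
    model, truth, = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    stem = build_stem_from_model(model)
    assert stem.n_tetrads == 3
    assert not any(t.planarity_flag for t in stem.tetrads)
    assert dirs_of(stem) == "dddd"
    assert {s.number: [g.position for g in s.guanosines]
            for s in stem.strands} == truth.strand_positions


def test_c1_out_of_plane_flag_with_independent_oracle():
    """Tilting one base's C1' 1.5 A off the base plane flags that tetrad;
    the flag matches an independent point-to-plane computation."""
    model, truth = build_stem(GeneratorSpec(
        topology="dddd", n_tetrads=3, c1_out_of_plane=(2, 3, 1.5)))
    stem = build_stem_from_model(model)
    assert [t.planarity_flag for t in stem.tetrads] == [False, True, False]
    flagged = stem.tetrads[1]
    dists = []
    for g in flagged.members_by_slot:
        pts = np.array([g.coord(a) for a in GUANINE_BASE_ATOMS])
        centroid, normal = fit_plane(pts)
        dists.append(abs(np.dot(g.coord("C1'") - centroid, normal)))
    assert max(dists) == pytest.approx(1.5, abs=0.05)


def test_isolated_guanines_are_not_a_g4():
    """Guanines without Hoogsteen geometry raise NotAG4."""
    rng = np.random.default_rng(0)
    residues = []
    for i in range(8):
        center = rng.normal(scale=30.0, size=3)
        atoms = {a: center + rng.normal(scale=1.0, size=3) for a in GUANINE_BASE_ATOMS}
        atoms["C1'"] = center + rng.normal(scale=1.0, size=3)
        residues.append(Residue(name="DG", chain_id="A", position=i + 1, atoms=atoms))
    model = StructureModel("scatter", "A", residues, ExperimentKind.synthetic)
    with pytest.raises(NotAG4Error):
        detect_tetrads(model)


def test_single_tetrad_rejected():
    """One tetrad is not a G4 stem and is rejected."""
    model, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=2))
    # keep only the guanosines of tetrad 1
    keep = {p for ps in [[1, 2], [4, 5], [7, 8], [10, 11]] for p in ps[:1]}
    model.residues = [r for r in model.residues if r.position in keep or r.name != "DG"]
    with pytest.raises(NotAG4Error):
        detect_tetrads(model)


@pytest.mark.parametrize("code", ALL_CODES)
def test_numbering_invariant_under_rigid_motion(code):
    """Strand numbers, directions and positions survive an arbitrary
    rotation + translation of the coordinates."""
    model, truth = build_stem(GeneratorSpec(topology=code, n_tetrads=3, seed=7))
    moved = rigid_transform(model, np.random.default_rng(11))
    stem = build_stem_from_model(moved)
    assert dirs_of(stem) == code
    assert {s.number: [g.position for g in s.guanosines]
            for s in stem.strands} == truth.strand_positions


@pytest.mark.parametrize("code", ["dddd", "duud"])
def test_upside_down_flip_is_undone(code):
    """Turning the stem upside down yields identical numbering and
    directions: the strand-1-down reorientation rule undoes the flip."""
    model, truth = build_stem(GeneratorSpec(topology=code, n_tetrads=3))
    import copy
    flipped = copy.deepcopy(model)
    rot = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
    for r in flipped.residues:
        for a in r.atoms:
            r.atoms[a] = rot @ r.atoms[a]
    stem = build_stem_from_model(flipped)
    assert dirs_of(stem) == code
    assert {s.number: [g.position for g in s.guanosines]
            for s in stem.strands} == truth.strand_positions
    assert stem.flipped  # it really was reoriented


@pytest.mark.parametrize(
    "kind", ["snapback_3bottom", "snapback_3top", "snapback_5bottom", "snapback_5top"])
def test_snapback_enumeration(kind):
    """Each extremity x tetrad combination is recognized as its own
    snapback kind."""
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3, snapback=(kind, 1)))
    stem = build_stem_from_model(model)
    kinds = [d.kind for s in stem.strands for d in s.discontinuities]
    assert kinds == [kind]


def test_one_nt_snapback_reverses_micro_direction():
    """A 1-nt 3'-bottom snapback guanosine is reversed (micro-direction up
    in a down strand), while a 2-nt snapback keeps the regular direction."""
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3,
                                            snapback=("snapback_3bottom", 1)))
    stem = build_stem_from_model(model)
    snap_strand = next(s for s in stem.strands if s.discontinuities)
    assert micro_directions(snap_strand) == ["down", "down", "up"]
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3,
                                            snapback=("snapback_3bottom", 2)))
    stem = build_stem_from_model(model)
    snap_strand = next(s for s in stem.strands if s.discontinuities)
    assert micro_directions(snap_strand) == ["down", "down", "down"]


def test_continuous_strand_micro_equals_global():
    model, _ = build_stem(GeneratorSpec(topology="dudu", n_tetrads=4))
    stem = build_stem_from_model(model)
    for s in stem.strands:
        assert micro_directions(s) == [s.direction] * 4


def test_bulge_detection():
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3, bulge=(2, 1, 3)))
    stem = build_stem_from_model(model)
    discs = [(d.kind, d.strand, d.tetrads) for s in stem.strands for d in s.discontinuities]
    assert discs == [("bulge", 2, (1, 2))]


def test_two_block_gap_and_blocks():
    """Linkers on all four strands between tetrads 2 and 3 split the stem
    into blocks [1-2] and [3-4]."""
    model, truth = build_stem(GeneratorSpec(topology="dddd/uuuu", n_tetrads=(2, 2)))
    stem = build_stem_from_model(model)
    assert stem.blocks == [(1, 2), (3, 4)]
    gap_strands = sorted({d.strand for s in stem.strands for d in s.discontinuities
                          if d.kind == "block_gap"})
    assert gap_strands == [1, 2, 3, 4]


def test_cross_chain_column_flagged():
    """A strand column mixing residues of two chains gets the cross_chain
    flag and an undetermined direction (interlaced-dimer style)."""
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    for pos in truth.strand_positions[3]:
        res = next(r for r in model.residues if r.position == pos)
        if pos == truth.strand_positions[3][0]:
            res.chain_id = "B"
    stem = build_stem_from_model(model)
    flagged = [s for s in stem.strands if any(
        d.kind == "cross_chain" for d in s.discontinuities)]
    assert len(flagged) == 1
    assert flagged[0].direction == "undetermined"


def test_inversion_of_polarity_detected():
    """Residue numbering that decreases over the first file-order residues
    then increases marks a 5'-5' inversion of polarity site."""
    model, _ = build_stem(GeneratorSpec(topology="dudu", n_tetrads=3))
    first = model.residues[:3]
    positions = [r.position for r in first]
    for r, p in zip(first, reversed(positions)):
        r.position = p
    model.residues.sort(key=lambda r: 0)  # keep file order as constructed
    stem = build_stem_from_model(model)
    kinds = {d.kind for d in stem.extra_discontinuities}
    assert "inversion_5p5p" in kinds


def test_hoogsteen_cycle_consistent_across_tetrads():
    """The strand membership read from the Hoogsteen cycles is the same
    rotation of slots in every tetrad of a block."""
    model, _ = build_stem(GeneratorSpec(topology="duud", n_tetrads=4))
    stem = build_stem_from_model(model)
    for t in stem.tetrads:
        assert set(t.members_by_slot) == set(t.cycle)
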