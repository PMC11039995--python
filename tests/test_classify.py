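"""Topology calls, single-tetrad deduction, loops, stacking, platypus."""

import itertools

import numpy as np
import pytest

from conftest import ALL_CODES, rigid_transform
from g4kit import GeneratorSpec, analyze
from g4kit import classify
from g4kit.geom import GrooveProfile
from g4kit.glyco import classify_gc
from g4kit.io import is_guanine
from g4kit.stem import build_stem_from_model
from g4kit.synthgen import TOPOLOGY_BY_CODE, build_stem


def full(**kw):
    model, truth = build_stem(GeneratorSpec(**kw))
    stem = build_stem_from_model(model)
    recs = {r.key: classify_gc(r) for r in model.residues if is_guanine(r)}
    return model, truth, stem, recs


@pytest.mark.parametrize("code", ALL_CODES)
def test_topology_code_name_bijection(code):
    _, truth, stem, recs = full(topology=code, n_tetrads=3)
    call = classify.topology(stem, recs)
    assert call.code == code
    assert call.name == TOPOLOGY_BY_CODE[code]


def test_two_block_topology_naming():
    _, truth, stem, recs = full(topology="dddd/uuuu", n_tetrads=(2, 2))
    call = classify.topology(stem, recs)
    assert call.per_block == ["dddd", "uuuu"]
    assert call.name == "parallel / parallel"


def test_single_tetrad_deduction_exhaustive():
    """All 16 s/a patterns map onto exactly 8 topologies, each hit by its
    two complementary patterns (enumeration oracle)."""
    hits = {}
    for letters in itertools.product("as", repeat=4):
        pattern = "".join(letters)
        call = classify.topology_from_single_tetrad(pattern)
        hits.setdefault(call.name, set()).add(pattern)
    assert len(hits) == 8
    for name, patterns in hits.items():
        assert len(patterns) == 2
        a, b = sorted(patterns)
        assert b == a.translate(str.maketrans("as", "sa"))
    with pytest.raises(ValueError):
        classify.topology_from_single_tetrad("a?as")


@pytest.mark.parametrize("code", ALL_CODES)
@pytest.mark.parametrize("phase", [0, 1])
def test_single_tetrad_agrees_with_full_stem(code, phase):
    """Every clean tetrad's pattern deduces the same topology as the full
    strand-direction analysis."""
    _, truth, stem, recs = full(topology=code, n_tetrads=3, gc_phase=phase)
    topo = classify.topology(stem, recs)
    for pattern in classify.gc_pattern(stem, recs)["patterns"]:
        assert classify.topology_from_single_tetrad(pattern).name == topo.name


def test_gc_pattern_predicted_pair_and_snapback_mismatch():
    """A 1-nt 3'-bottom snapback puts one syn in the bottom tetrad of a
    parallel stem; the mismatch is annotated as a micro-direction effect."""
    _, truth, stem, recs = full(topology="dddd", n_tetrads=3)
    rep = classify.gc_pattern(stem, recs)
    assert rep["predicted"] == ("aaaa", "ssss")
    assert rep["patterns"] == ["aaaa"] * 3 and not rep["mismatches"]

    _, truth, stem, recs = full(topology="dddd", n_tetrads=3,
                                snapback=("snapback_3bottom", 1))
    rep = classify.gc_pattern(stem, recs)
    bottom = rep["patterns"][-1]
    assert bottom.count("s") == 1
    assert any(m["micro_effect"] for m in rep["mismatches"])


@pytest.mark.parametrize(
    "code,combo",
    [
        ("dddd", "-p-p-p"),
        ("dudu", "+l+l+l"),
        ("duud", "-ld+l"),
        ("dduu", "-pd+p"),
        ("ddud", "-p-l-l"),
        ("dddu", "-p-p-l"),
        ("dudd", "-l-l-p"),
        ("duuu", "+l+p+p"),
    ],
)
def test_loop_combinations_match_their_topologies(code, combo):
    _, truth, stem, recs = full(topology=code, n_tetrads=3)
    ann = classify.annotate_loops(stem)
    assert ann.combination == combo == truth.loop_combination


def test_zero_length_propeller_is_v_shaped():
    _, truth, stem, recs = full(topology="dddd", n_tetrads=3,
                                loop_lengths={"p": 0})
    ann = classify.annotate_loops(stem)
    assert ann.combination == "-v-v-v"


def test_mirror_flips_loop_signs_not_types():
    """Reflecting the coordinates reverses every loop progression sign but
    leaves the loop types unchanged."""
    model, truth, stem, recs = full(topology="dudu", n_tetrads=3)
    ann = classify.annotate_loops(stem)
    mirrored = rigid_transform(model, np.random.default_rng(9), mirror=True)
    m_stem = build_stem_from_model(mirrored)
    m_ann = classify.annotate_loops(m_stem)
    assert [l.kind for l in ann.loops] == [l.kind for l in m_ann.loops]
    flip = {"+": "-", "-": "+", "": ""}
    assert [flip[l.sign] for l in ann.loops] == [l.sign for l in m_ann.loops]


@pytest.mark.parametrize(
    "code,expected_type",
    [("dddd", 1), ("dudu", 3), ("duud", 3), ("ddud", 2), ("duuu", 2)],
)
def test_stacking_types_by_topology(code, expected_type):
    """Parallel strands stack type 1 (same gcs), antiparallel type 3
    (alternating), hybrids type 2 (similar and alternate)."""
    _, truth, stem, recs = full(topology=code, n_tetrads=3)
    types = classify.stacking_types(stem, recs)
    assert set(types.per_strand.values()) == {expected_type}


def test_two_tetrad_stacking_collapse():
    """At T=2 the scheme collapses: same -> 1, different -> 3."""
    _, truth, stem, recs = full(topology="dddd", n_tetrads=2)
    types = classify.stacking_types(stem, recs)
    assert set(types.per_strand.values()) == {1} and types.two_tetrad_note
    _, truth, stem, recs = full(topology="dudu", n_tetrads=2)
    types = classify.stacking_types(stem, recs)
    assert set(types.per_strand.values()) == {3}


def _profile(sig):
    p = GrooveProfile(atom_kind="C5'", per_tetrad=np.zeros((4, 3)))
    p.signature_threshold = sig
    return p


def _topo(code, name=None, per_block=None):
    return classify.TopologyCall(code=code, name=name or TOPOLOGY_BY_CODE.get(code, code),
                                 per_block=per_block or [code])


def test_platypus_on_contradictory_characteristics():
    """Chair-like directions and loops with hybrid1-like gc pattern and
    threshold signature: the implied topology sets do not intersect."""
    report = classify.platypus_check(
        _topo("dudu"),
        {"patterns": ["aasa", "aasa"], "predicted": None, "mismatches": []},
        _profile("iwni"),
        classify.LoopAnnotation(loops=[
            classify.Loop(kind="l", sign="-", length=3, strands=(1, 2), positions=(0, 0)),
            classify.Loop(kind="l", sign="-", length=3, strands=(2, 3), positions=(0, 0)),
            classify.Loop(kind="l", sign="-", length=3, strands=(3, 4), positions=(0, 0)),
        ]),
    )
    assert report.is_platypus
    assert report.implied["strand_directions"] == {"antiparallel-chair"}
    assert report.implied["gc_pattern"] == {"hybrid1"}


def test_consistent_structure_is_not_platypus():
    model, truth = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    rep = analyze(model)
    assert not rep.platypus.is_platypus
    assert rep.platypus.consistent == {"parallel"}


def test_undetermined_direction_with_consistent_gc_not_platypus():
    """An undetermined strand direction (interlaced-dimer style) with a
    consistent hybrid1 gc pattern and signature is not a platypus; the gc
    pattern supplies the topology suggestion."""
    report = classify.platypus_check(
        _topo("dd?d", name="undetermined", per_block=["dd?d"]),
        {"patterns": ["aasa", "aasa"], "predicted": None, "mismatches": []},
        _profile("iwni"),
        classify.LoopAnnotation(loops=[]),
    )
    assert not report.is_platypus
    assert report.consistent == {"hybrid1"}
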