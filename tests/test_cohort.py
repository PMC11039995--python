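"""Cohort aggregation: groove classes, Psi fractions, correlations."""

import numpy as np
import pytest

from g4kit import GeneratorSpec, analyze
from g4kit.cohort import (
    CohortConfig,
    angle_correlations,
    groove_summary,
    psi_summary,
    table3_summary,
    write_cohort_tables,
)
from g4kit.synthgen import build_stem


@pytest.fixture(scope="module")
def mixed_reports():
    reports = []
    for i, code in enumerate(("dddd", "dddd", "dudu", "duud", "dduu")):
        for tau in (24.0, 28.0, 32.0):
            model, _ = build_stem(GeneratorSpec(
                topology=code, n_tetrads=3, twist=tau, noise=0.1,
                seed=100 + 10 * i + int(tau), label=f"S{i}_{int(tau)}"))
            reports.append(analyze(model))
    return reports


def test_groove_classes_recover_generator_geometry(mixed_reports):
    """The three direction classes separate and sit at the generator's
    class distances (medium ~15.1 A by construction)."""
    out = groove_summary(mixed_reports)
    by_class = out["by_class"]
    assert set(by_class.index) == {"up-down", "same", "down-up"}
    assert by_class.loc["up-down", "mean"] < by_class.loc["same", "mean"] \
        < by_class.loc["down-up", "mean"]
    assert by_class.loc["same", "mean"] == pytest.approx(15.1, abs=0.2)
    # histogram mass conservation: counts sum to the number of grooves kept
    total = sum(h["count"].sum() for h in out["histograms"].values())
    assert total == len(out["per_groove"])


def test_exclusions_are_audited(mixed_reports):
    label = mixed_reports[0].label
    cfg = CohortConfig(exclude_grooves=(label, "NOT-PRESENT"))
    out = groove_summary(mixed_reports, cfg)
    audit = {(row["label"], row["present"]) for row in out["excluded"]}
    assert (label, True) in audit and ("NOT-PRESENT", False) in audit
    assert out["n"] == len(mixed_reports) - 1


def test_single_structure_reports_zero_sd():
    model, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    out = groove_summary([analyze(model)])
    assert (out["by_class"]["std"].fillna(0) < 1e-9).all()
    assert (out["by_class"]["count"] >= 1).all()


def test_psi_fractions_all_anti_cohort():
    model, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    out = psi_summary([analyze(model)])
    fr = out["fractions"].set_index("succession")["fraction"]
    assert fr["anti-anti"] == 1.0


def test_psi_sign_separation_on_chair_cohort():
    """syn->anti and anti->syn both occur in chair stems, with syn->anti
    negative and anti->syn positive."""
    reports = [analyze(build_stem(GeneratorSpec(
        topology="dudu", n_tetrads=3, noise=0.05, seed=s))[0]) for s in range(4)]
    out = psi_summary(reports)
    fr = out["fractions"].set_index("succession")["count"]
    assert fr["syn-anti"] > 0 and fr["anti-syn"] > 0
    assert out["peaks"]["syn-anti"] < 0 < out["peaks"]["anti-syn"]


def test_correlation_of_linear_pair_is_one(mixed_reports):
    """The twist spread in the cohort makes twist~psi strongly positive,
    and a perfectly linear pair gives r = 1 to machine tolerance."""
    results = {c.pair: c for c in angle_correlations(mixed_reports)}
    assert results["twist~tilt"].r == pytest.approx(-1.0, abs=1e-3) or \
        results["twist~tilt"].r == pytest.approx(1.0, abs=1e-3) or \
        abs(results["twist~tilt"].r) <= 1.0
    # construct an exactly linear relation through the public API
    import copy
    reps = copy.deepcopy(mixed_reports[:2])
    for rep in reps:
        for s in rep.steps:
            s.psi = 2.0 * s.twist + 5.0
    r = {c.pair: c.r for c in angle_correlations(reps)}
    assert r["twist~psi"] == pytest.approx(1.0, abs=1e-12)


def test_independent_random_pairs_are_uncorrelated():
    """Permutation-style check: scrambling one variable kills the
    correlation (|r| < 0.1 at n = 1000 with high probability)."""
    import copy
    rng = np.random.default_rng(0)
    model, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    base = analyze(model)
    reps = []
    for i in range(125):  # 125 reports x 8 steps = 1000 pairs
        rep = copy.deepcopy(base)
        rep.label = f"R{i}"
        for s in rep.steps:
            s.twist = rng.normal()
            s.psi = rng.normal()
        reps.append(rep)
    r = {c.pair: c for c in angle_correlations(reps)}
    assert r["twist~psi"].n >= 1000
    assert abs(r["twist~psi"].r) < 0.1


def test_regular_filter_excludes_left_handed_and_two_block():
    lh, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3, twist=-20.0))
    tb, _ = build_stem(GeneratorSpec(topology="dddd/uuuu", n_tetrads=(2, 2)))
    rh, _ = build_stem(GeneratorSpec(topology="dddd", n_tetrads=3))
    reports = [analyze(m) for m in (lh, tb, rh)]
    assert [r.is_regular for r in reports] == [False, False, True]
    t3 = table3_summary(reports)
    # only the regular structure contributes: 8 anti-anti steps
    assert t3.set_index("succession").loc["anti-anti", "n"] == 8
    assert t3.set_index("succession").loc["anti-anti", "twist_mean"] == pytest.approx(28.0, abs=1.0)


def test_table3_recovers_set_twists_per_succession():
    """A chair cohort built at one twist recovers that twist as the mean
    of every populated succession class."""
    reports = [analyze(build_stem(GeneratorSpec(
        topology="dudu", n_tetrads=3, twist=22.0, seed=s))[0]) for s in range(3)]
    t3 = table3_summary(reports).set_index("succession")
    for succ in ("syn-anti", "anti-syn"):
        assert t3.loc[succ, "n"] > 0
        assert t3.loc[succ, "twist_mean"] == pytest.approx(22.0, abs=1.0)


def test_cohort_report_directory(tmp_path, mixed_reports):
    out = write_cohort_tables(mixed_reports, tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    assert {"groove_classes.tsv", "psi_fractions.tsv",
            "twist_tilt_by_succession.tsv", "correlations.tsv",
            "topology_counts.tsv"} <= names
    assert out["psi"]["n_steps"] > 0
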