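import numpy as np
import pytest

from g4kit import GeneratorSpec, analyze
from g4kit.glyco import classify_gc
from g4kit.io import is_guanine
from g4kit.stem import build_stem_from_model
from g4kit.synthgen import build_stem

ALL_CODES = ("dddd", "dudu", "duud", "dduu", "ddud", "dddu", "dudd", "duuu")


@pytest.fixture(scope="session")
def make_stem():
    """Build a synthetic model + ground truth and the assembled stem."""

    def _make(**kwargs):
        spec = GeneratorSpec(**kwargs)
        model, truth = build_stem(spec)
        stem = build_stem_from_model(model)
        return model, truth, stem

    return _make


@pytest.fixture(scope="session")
def make_report():
    def _make(**kwargs):
        spec = GeneratorSpec(**kwargs)
        model, truth = build_stem(spec)
        return analyze(model), truth

    return _make


@pytest.fixture(scope="session")
def gc_map():
    def _map(model):
        return {r.key: classify_gc(r) for r in model.residues if is_guanine(r)}

    return _map


def rigid_transform(model, rng=None, mirror=False):
    """Apply a random rotation + translation (optionally a mirror) to every
    atom of a model, in place-free copy."""
    import copy

    rng = rng or np.random.default_rng(0)
    # random rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    if mirror:
        q = q @ np.diag([1.0, 1.0, -1.0])
    t = rng.normal(scale=20.0, size=3)
    out = copy.deepcopy(model)
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = q @ res.atoms[name] + t
    return out
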