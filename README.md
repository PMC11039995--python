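# g4kit

Structural characterization of intramolecular G-quadruplexes (G4s) from
3D coordinates.

A G4 stem is a stack of guanine tetrads: four guanines per layer joined
in a Hoogsteen hydrogen-bond cycle (each donates its Watson–Crick edge
N1/N2 to the next one's Hoogsteen edge O6/N7), with the vertical columns
of stacked guanosines forming four strands that delimit four grooves.
g4kit is a library for structural biologists who need the quantities
this formalism defines, computed consistently over one structure or a
whole set:

- **Tetrad detection and strand numbering.** Tetrads are found from
  heavy-atom Hoogsteen geometry; the stem is oriented so that strand 1 —
  the column holding the 5′-most stem guanosine — runs down, and strands
  2–4 follow the Hoogsteen pairing (clockwise viewed from the top for
  regular structures; anticlockwise numbering is detected and flagged).
- **Topology.** The down/up code of the four strands, one of eight
  classes: `dddd` parallel, `dudu` antiparallel-chair, `duud`
  antiparallel-basket, `dduu` antiparallel-basket2, `ddud`–`duuu`
  hybrid1–4. Two-block stems (≥3 strands interrupted between the same
  two tetrads) are classified per block.
- **Glycosidic configurations.** χ = O4′–C1′–N9–C4 mapped to (0°, 360°]:
  *syn* for χ ∈ (0, 140], *anti* for χ ∈ (152, 300], with distance
  fallbacks (H1′–H8, then N3–O5′) in the two indeterminacy gaps. Because
  gc and strand direction are geometrically coupled, one clean tetrad's
  s/a pattern deduces the full topology.
- **Groove widths.** Per-groove mean of like-atom distances (C5′, C3′ or
  P) between the delimiting guanosines of each tetrad. Adjacent strand
  directions set the class — up-down narrow (~11.4 Å), same-direction
  medium (~15.1 Å), down-up wide (~17.3 Å) — giving each topology a
  4-letter n/i/w signature. Minimum groove distances (cross-tetrad
  search) estimate the space actually available to a lateral ligand.
- **Stacking geometry.** The pseudo-dihedral Ψ = N1(i)–N9(i)–N9(j)–N1(j)
  of stacking guanines read along the chain, per-step helical twist
  (positive = right-handed) and tilt, and their pseudo-average
  (twist + tilt)/2 ≈ 40° in regular stems — a cheap diagnostic for
  structures whose first stem-guanine is built in the reversed
  orientation (the pseudo-average leaves the 25–55° band).
- **Loops and discontinuities.** Propeller / lateral / diagonal /
  V-shaped / internal loops with bottom-to-top progression signs,
  bulges, the four snapback kinds, inter-block gaps, 5′–5′ inversions,
  cross-chain columns.
- **Platypus detection.** Structures whose characteristics (directions,
  gc pattern, measured groove signature, loop combination) point at
  different topologies.
- **Synthetic structures.** `g4kit.synthgen` builds idealized stems for
  any topology, gc pattern, twist/rise, handedness and discontinuity,
  with ground-truth labels — every pipeline stage is testable offline.

## Worked example

```python
from g4kit import GeneratorSpec, analyze
from g4kit.synthgen import build_stem

model, truth = build_stem(GeneratorSpec(topology="hybrid1", n_tetrads=3))
report = analyze(model)          # or: g4kit.analyze_paths(["file.pdb"])
```

Running `python examples/characterize_structure.py` (which does exactly
this) prints:

```
topology           : hybrid1  (strand directions ddud)
handedness         : right
gc pattern         : ssas aasa aasa  (tetrads top to bottom)
groove widths C5'  : [15.1, 18.1, 11.9, 15.1] A
groove signature   : iwni (n = narrow ~11.4 A, i = medium ~15.1 A, w = wide ~17.3 A)
perimeter          : 60.2 A (sum of the four widths; ~59 A in real stems)
loop combination   : -p-l-l (p propeller, l lateral, d diagonal; +/- = progression viewed bottom-up)
stacking types     : {1: 2, 2: 2, 3: 2, 4: 2} (1 same gcs, 2 mixed, 3 alternating along each strand)
mean twist         : 28.0 deg (right-handed when positive)
pseudo-average     : 39.1 deg (regular stems sit near 40)
```

The `ssas/aasa` pattern, the `iwni` signature and the `-p-l-l` loop
combination are the hybrid1 fingerprints; any one of them would identify
the topology on its own, which is why their disagreement (a "platypus"
structure) is worth flagging.

The other scripts in `examples/` cover batch PDB analysis with failure
handling, single-tetrad topology deduction, cohort statistics (groove
classes, Ψ distributions, twist/tilt per gc succession), and the
reversed-first-guanine diagnostic.

Real PDB entries are analyzed the same way: `g4kit.load_structures`
applies the standard curation rule (first model of a multi-model NMR
ensemble; every chain of an X-ray file) and `analyze_paths` maps the
pipeline over files, skipping and logging the ones that fail.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: it
generates a seeded synthetic cohort spanning all eight topologies, both
complementary gc patterns, 2–4 tetrads, plus two-block, snapback, bulge
and reversed-first-guanine cases; writes the cohort to PDB; re-reads and
analyzes every file; and aggregates the cohort tables (groove classes,
Ψ fractions, twist/tilt table, correlations).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the geometric model, every convention and
tolerance the package fixes (hydrogen-bond cutoffs, the strand-numbering
rule, twist/tilt definitions, glyco fallback calibration), what the
synthetic generator does and does not emulate, and known limitations.
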