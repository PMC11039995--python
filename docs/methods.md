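# Methods

This note records the geometric model behind g4kit, the conventions and
tolerances it fixes where the G4 formalism leaves them open, what the
synthetic generator emulates, and the limits of what a passing test
establishes.

## Coordinate model and curation

PDB files are parsed with Bio.PDB; each chain of each retained model
becomes one `StructureModel`. Multi-model (NMR/EM) entries contribute
only the first model — solution ensembles would otherwise multiply-count
one structure — while X-ray entries contribute every chain, because the
chains coexist in the crystal. Waters and ions are kept apart from the
nucleic residues. Residues are identified by (chain, number, insertion
code); negative numbers and insertion codes are accepted. Guanine
recognition is by base-atom content (N9, C8, N7, C5, C6, O6, N1, C2,
N2, N3 all present), so modified guanines qualify under any residue
name and a guanine missing a Hoogsteen-edge atom does not. All geometry
uses heavy atoms; hydrogens matter only for the glycosidic fallback.

## Tetrad detection

A directed Hoogsteen candidate edge runs from donor G to acceptor G when
d(N1, O6) ≤ 3.5 Å or d(N2, N7) ≤ 3.6 Å (both within cutoff preferred;
`HbondParams.require_both` demands it). Tetrads are directed 4-cycles in
this graph (networkx cycle search); a guanine claimed by two cycles is
resolved by the smaller summed H-bond distance, and a persistent tie
raises an ambiguity error. Fewer than two tetrads is rejected: a single
tetrad is not a G4 stem. Stacking adjacency between tetrads uses
centroid distance ≤ 5.5 Å and |cos| of the normals ≥ 0.7; the adjacency
graph must form a simple path, whose traversal is the stacking order.
These cutoffs are declared defaults (the formalism assumes stacking
without defining it) and sit in `g4kit.config`.

A tetrad is flagged non-planar when any member's C1′ lies more than
0.9 Å (configurable) from that base's least-squares plane — the
pathology that makes downstream gc and groove values unreliable.

## Strand numbering and orientation

Columns of stacked guanosines are tracked through the stack by optimal
assignment on C1′ proximity (C1′ because its azimuth varies least
between syn- and anti-parity tetrads; base centroids mis-assign at high
twist). Strand 1 is the column holding the 5′-most stem guanosine; if
its chain positions decrease from the current top to bottom, the whole
stem is flipped so that strand 1 runs down. Strands 2–4 then follow the
Hoogsteen cycle of the top tetrad **in the donor→acceptor direction when
the first stem-guanosine is anti, and the acceptor→donor direction when
it is syn**.

That gc-dependence is forced by geometry: a planar tetrad of bases
presenting their "anti-in-a-down-strand" face can only close its donor
cycle clockwise (viewed from the top), and a tetrad of flipped bases
only anticlockwise. The rule therefore yields clockwise numbering for
every regular structure regardless of which pattern phase its top tetrad
has, and anticlockwise numbering exactly when the first stem-guanine is
oriented opposite to usual — which is how such structures are flagged
(`Stem.anticlockwise`, checked algebraically: the cross product of the
centroid→strand-1 and centroid→strand-2 vectors must align with the
top→bottom normal).

Strand directions are read from chain-position progression only
(chain-adjacent steps vote; all steps as fallback), never from base
geometry, so discontinuities displace but do not break direction calls.
A column mixing residues of two chains (interlaced dimers) is flagged
`cross_chain` with an undetermined direction; completion from partner
chains is out of scope.

## Discontinuities and micro-directions

Between vertically adjacent guanosines of one strand, non-consecutive
chain positions mark a discontinuity. They are classified in order:
inter-block gap when ≥3 strands are interrupted between the same two
tetrads (the stem splits into blocks there); snapback when a
chain-terminal run of the strand occupies the first or last tetrad
(giving the four kinds 3′/5′ × top/bottom — extremity runs take
precedence over the bulge reading, so a bulge flanking the chain end is
not distinguishable from a snapback); otherwise bulge when the
intervening residues are non-stem and the chain continues in the
strand's direction, and internal loop when the chain jumps against it.
A 5′–5′ inversion of polarity is recognized from file order versus
residue numbering at the 5′ terminus; the reversed linkage itself is not
representable in coordinates.

Micro-directions refine the per-strand direction per guanosine: inside
a chain-contiguous run the step sign decides; an isolated single-residue
snapback guanosine is reversed relative to its strand (its loop turns
the nucleoside around), while a 2-residue snapback keeps the regular
orientation — which is exactly why 1-nt snapbacks carry the "wrong" gc
for their tetrad pattern and longer ones need not.

## Glycosidic configuration

χ is the IUPAC purine torsion O4′–C1′–N9–C4, mapped to (0°, 360°] so
the published intervals apply verbatim: syn (0, 140], anti (152, 300],
half-open at both ends. In the gaps (140, 152] and (300, 360] the call
falls back to d(H1′, H8) < 3.25 Å → syn when hydrogens exist, else
d(N3, O5′) < 6.44 Å → syn. The thresholds are midpoints between the
values measured on generated guanosines built at unambiguous χ (syn
60°: 2.58 / 5.59 Å; anti 240°: 3.92 / 7.29 Å) and are frozen in
`g4kit.config`; both inequality directions agree with the physical
contacts (the short syn H8–H1′ NOE distance, the syn O5′H···N3
interaction). Every record stores the rule that decided it.

## Grooves

Groove g lies between strands g and g+1 (groove 4 wraps to strand 1).
Its per-tetrad distance is between like atoms of the two delimiting
guanosines in the same tetrad; the width is the mean over tetrads
(missing atoms drop out of the mean and are logged as NaN entries), the
perimeter is the exact sum of the four widths. C5′ is the default atom;
C3′ and P profiles are always computed alongside.

Two signatures are reported. The direction-based letters follow the
adjacent strand directions (up-down → n, down-up → w, same → i) and are
tautological with the topology; the threshold-based letters come from
the width values with class boundaries at the midpoints of the cohort
class means (13.25 and 16.2 Å on the C5′ scale — the C5′ calibration is
also applied to C3′/P profiles, a documented approximation). Platypus
detection uses the threshold letters, since only a measured signature
can contradict the strand directions.

Minimum groove distances capture tilt-induced cross-tetrad contacts:
for each tetrad t ≥ 2 and groove, the minimum like-atom distance between
one delimiting strand's guanosine at t and the other strand's
guanosines at t−1, t, t+1 (both roles; window configurable, adjacent
layers by default because tilt contacts are between neighbours). The
top tetrad is skipped — its minimum is mostly the same-tetrad distance.
C3′ is the default atom here, being united to the nucleoside core.

## Ψ, twist, tilt and the pseudo-average

Ψ = dihedral N1(i)–N9(i)–N9(j)–N1(j) for stacking guanines ordered
along the chain; the dihedral is invariant under full order reversal,
so the value is reading-direction-free while the succession label
(syn→anti vs anti→syn) is not — reading along the chain is what keeps
the succession classes separated in Ψ.

Per strand and per adjacent tetrad pair within a block, with the pair
chain-ordered: twist is the signed angle between the tetrad-centroid→C1′
projections about the local stem axis, the sign taken about the axis
oriented along the strand's own progression, so all four strands of a
right-handed stem measure positive and equal twists. Tilt is the angle
of the C1′→C1′ step to the axis, reported acute, then replaced by its
supplement when the step's twist sign disagrees with the stem's
numbering sense (clockwise +1 / anticlockwise −1). The exact reference
definitions are not recoverable from the formalism alone; this
convention is fixed here because it reproduces the four observable
regimes: regular right-handed stems have acute tilts and pseudo-average
(twist + tilt)/2 ≈ 40°; anticlockwise-numbered right-handed stems go
obtuse (pseudo-average > 60°); anticlockwise left-handed stems come out
low (< 20°); clockwise left-handed stems go obtuse with pseudo-average
near 40. The default diagnostic band is 25–55°.

Handedness is right/left when every step twist is positive/negative,
otherwise mixed. The regular-G4 filter used by the cohort layer is:
one block, right-handed, no 5′–5′ inversion.

## Loops

Connectors between chain-consecutive stem guanosines of different
strands are typed from the strand adjacency and tetrad levels of their
anchors: lateral (adjacent strands, same tetrad), diagonal (opposite
strands, same tetrad, unsigned), propeller (adjacent strands, different
tetrads), V-shaped (0-nt propeller: a lone phosphate), linker (across a
block gap). The progression sign is the rotation sense of the
exit→entry azimuth about the stem axis viewed bottom-to-top, clockwise
'+' — realized algebraically as the sign of the signed angle about the
bottom-up axis. Within-strand connectors are bulges/internal loops, not
loops. Combination strings list the basic loops in chain order;
snapback-induced loops are marked separately.

## Stacking types and platypus logic

Per strand, the gc succession read along the chain is type 1 (only
similar), 2 (similar and alternate) or 3 (only alternate); two-tetrad
strands collapse to same → 1, different → 3 (a flagged convention —
the 3-type scheme is defined on ≥3 tetrads). Canonically parallel
stems are type 1, hybrids 2, antiparallel 3.

Platypus detection maps each available characteristic to its implied
topology set — strand directions directly, each clean tetrad's gc
pattern through the single-tetrad rule, the threshold groove signature
through the signature table (iwin and iwii both mean basket2), the
basic loop combination through the observed combination table — and
declares a platypus when the intersection is empty. An undetermined
direction with otherwise consistent characteristics is not a platypus;
the gc pattern then supplies the topology suggestion.

## The synthetic generator

`synthgen` realizes the stated geometry directly. A 2D guanine template
(standard base reference frame) is posed by a small least squares so
that the C4 tetrad closes its Hoogsteen cycle at d(N1···O6) = 2.92 Å,
d(N2···N7) = 2.86 Å with O6 ringing the axial cation channel at 2.4 Å
and C1′ ~7–8 Å out; the flipped-face pose is solved with the same
constraints plus a pull toward the unflipped C1′ azimuth, which is what
keeps the per-step twist well defined in stems whose tetrads alternate
parity. Tetrads stack at the requested rise (default 3.3 Å) and twist
(default 28°, the observed anti-anti mean; positive = right-handed).
The base-flip parity of a tetrad is (gc is syn) XOR (strand is up),
necessarily uniform within a tetrad — the generator refuses patterns
that violate this coupling, which is the same rule that lets one tetrad
determine the topology. Default gc patterns per topology: parallel
all-anti, antiparallel strictly alternating from a syn top tetrad,
hybrids syn-top then anti (`gc_phase=1` complements every tetrad).

Sugars are minimal: O4′ and H1′ are placed by internal coordinates off
the actual base so χ is exact (H1′ at χ+120°, the D-chirality offset
measured on the reference nucleotide geometry); C5′/C3′/P sit at fixed
radii (C5′ at 15.1/√2 ≈ 10.68 Å so same-direction grooves measure
medium) with direction-dependent azimuthal offsets (±12° for C5′) that
realize narrow ≈ 11.9 Å and wide ≈ 18.1 Å for up-down and down-up
pairs, and z-offsets toward the 5′/3′ sides following the guanosine's
micro-direction. Loop residues are placeholders (P, C5′, C1′ on an arc
outside the stem) that carry chain numbering, not conformations.
Reversed-first-guanine stems are built by flipping every base's face
relative to what its gc implies, which reverses the donation sense and
hence the numbering, exactly as in the real pathology.

Without tuning, the generated Ψ values fall at ≈ −24° (syn→anti), +22°
(anti-anti, right-handed), +60° (anti→syn), +19° (syn-syn) —
reproducing the observed sign structure and ordering.

What the generator does **not** emulate: sugar puckers and a
connected sugar-phosphate backbone (C1′–C5′ covalent geometry is not
respected); the empirical anticorrelation between twist and tilt (tilt
here is a rigid function of twist and rise, so the ≈40° pseudo-average
holds at observed twists 17–34°, not across the whole recovery sweep);
thermal width scatter beyond isotropic jitter; mixed-parity tetrads
(real platypus structures violate the coupling the generator enforces —
platypus logic is therefore exercised at the classification level);
5′–5′ linkage chemistry. A green synthetic test establishes that the
pipeline recovers the formalism's labels from geometry obeying the
formalism; agreement with any particular experimental cohort is a
separate, data-dependent question.

## Cohort layer

Aggregation pools per-structure reports: groove statistics by direction
class (0.1 Å histograms), Ψ fractions and histograms per succession
(1° bins; peaks as the mode after a 5-bin moving average), the
twist/tilt table per succession, and Pearson correlations (scipy)
between twist, tilt, Ψ and the minimum groove distance (paired to a
step as the strand's clockwise-side groove at the step's deeper
tetrad). Exclusion lists are per-analysis, and every exclusion is
audited with its reason and whether the label was present. p-values
below 10⁻¹⁵ are reported as "<1e-15". Correlations pool all steps of
the regular structures rather than per-structure means (a flag-level
choice documented here; pooling is the default because step counts per
structure are small and unequal).

## Numerical notes

Angles are degrees everywhere; dihedrals are IUPAC-signed in
(−180°, 180°] (cross-checked against Bio.PDB) and χ is wrapped to
(0°, 360°]. Tetrad planes are SVD fits; stem axes are tetrad-centroid
differences; degenerate axes (coincident centroids) raise. PDB output
is 3-decimal; round trips preserve coordinates at that precision.
Half-open interval boundaries are honored exactly (χ = 140° is syn,
152° is indeterminate, 300° is anti).
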