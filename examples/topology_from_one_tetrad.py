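"""Deduce the topology from the gc pattern of a single tetrad.

Because adjacent guanines share their glycosidic configuration exactly
when their strands run the same way, one clean tetrad's syn/anti pattern
(read in strand order, strand 1 down) pins the whole topology.  The
check below deduces the topology from each tetrad of a generated basket
stem and from all 16 possible patterns.
"""

import itertools

from g4kit import GeneratorSpec, analyze, topology_from_single_tetrad
from g4kit.synthgen import build_stem

model, truth = build_stem(GeneratorSpec(topology="antiparallel-basket", n_tetrads=3))
report = analyze(model)
print(f"full-stem topology: {report.topology.name}")
for i, pattern in enumerate(report.gc_patterns, start=1):
    call = topology_from_single_tetrad(pattern)
    print(f"  tetrad {i} pattern {pattern} -> {call.name} ({call.code})")

print("\nall 16 patterns (each topology is hit by two complementary ones):")
for letters in itertools.product("as", repeat=4):
    pattern = "".join(letters)
    call = topology_from_single_tetrad(pattern)
    print(f"  {pattern} -> {call.code}  {call.name}")
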