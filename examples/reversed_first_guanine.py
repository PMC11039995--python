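"""The pseudo-average diagnostic for a reversed first stem-guanine.

A stem whose first stem-guanosine has its hydrogen-bond donors oriented
opposite to usual gets numbered anticlockwise, and its tilt angles come
out supplementary.  The mean of (twist + tilt)/2 -- normally ~40 degrees
-- then leaves the 25-55 band, which makes the defect detectable without
visualizing the structure.
"""

import numpy as np

from g4kit import GeneratorSpec, analyze
from g4kit.synthgen import build_stem

cases = [
    ("regular right-handed", dict(twist=28.0)),
    ("reversed, right-handed", dict(twist=28.0, reversed_first_guanine=True)),
    ("reversed, left-handed", dict(twist=-20.0, reversed_first_guanine=True)),
]
for name, kw in cases:
    model, _ = build_stem(GeneratorSpec(topology="parallel", n_tetrads=3, **kw))
    rep = analyze(model)
    pa = np.mean([s.pseudo_average for s in rep.steps])
    print(f"{name:24s}: numbering {'anticlockwise' if rep.anticlockwise else 'clockwise':13s} "
          f"pseudo-average {pa:6.1f} deg  flagged={rep.reversed_first_guanine}")
print("\nvalues above 55 or below 25 flag a reversed first stem-guanine")
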