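"""Haar wavelet features distinguish local switches from global shifts.

Two 4x4 expression grids with the same overall mean: one globally flat,
one with a localized 2x2 "switch" (two cells up, two down).  The finest
mean-of-differences features light up only for the switch, while the
coarse mean-of-means feature cannot see it — exactly the complementarity
of high-pass and low-pass filters the transform provides.
"""

import numpy as np

import pathwave as pw

flat = np.zeros((4, 4))
switch = np.zeros((4, 4))
switch[0, 0] = switch[1, 0] = +2.0   # two reactions up ...
switch[0, 1] = switch[1, 1] = -2.0   # ... their neighbors down

for name, grid in [("flat", flat), ("switch", switch)]:
    feats = pw.decompose(grid)
    top = max(feats, key=lambda f: abs(f.value))
    coarse = [f for f in feats if f.level == max(x.level for x in feats)
              and f.kind == "mean_of_means"][0]
    print(f"{name:7s} strongest feature: {top.kind} at level {top.level} "
          f"section {top.section} = {top.value:+.2f}; "
          f"global mean feature = {coarse.value:+.2f}")
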