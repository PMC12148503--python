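"""Background χ3 distribution and outlier scoring.

Samples a seeded wrapped-normal χ3 ensemble shaped like the survey
background of well-resolved disulfides (bimodal near ±90°), bins it
with 5° bins over [-180, 180], and scores a syn-periplanar χ3 = 0°
against it: the rarity score is the fraction of the background in bins
no more populated than the query's bin.
"""

import numpy as np

from ssbond import (EnsembleSpec, build_histogram, empirical_percentile,
                    sample_dihedral_ensemble)

spec = EnsembleSpec(n=10_000, chi3=((95.0, 8.0, 0.5), (-87.0, 8.0, 0.5)), seed=1)
records = sample_dihedral_ensemble(spec)
hist = build_histogram(records, "chi3")

order = np.argsort(hist.counts)[::-1]
modes = sorted(float(c) for c in hist.centers[order[:2]])
print(f"records               : {hist.n_records}")
print(f"histogram modes (deg) : {modes}  (truth: -87, +95)")
for angle in (-87.0, 0.0):
    s = empirical_percentile(angle, hist)
    print(f"chi3 = {angle:6.1f} deg -> bin freq {s.bin_freq:.4f}, "
          f"rarity {s.rarity:.4f}")
print("A rarity near 0 marks an extreme outlier: essentially no relaxed "
      "disulfide in the background adopts a syn-periplanar chi3.")
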