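"""Splitting eDNA copies between alewife and blueback from peak heights.

Simulates a Sanger chromatogram of a 30:70 alewife:blueback mixture with
a strong base-specific signal bias (T peaks read 2x brighter than C),
then recovers the mixture with the corrected peak-height-ratio estimator
at the diagnostic bp-104 SNP and apportions a 10,000-copy detection.
Also reruns the published mock-mixture validation: regressing inferred
on known proportions across seven mixture levels.
"""

import numpy as np

from alosaedna import classify_and_apportion, corrected_ratio, correction_factors, mixture_validation
from alosaedna.simulate import simulate_chromatogram

rng = np.random.default_rng(7)
bias = {"T": 2.0, "C": 1.0}

table = simulate_chromatogram(0.30, rng=rng, bias=bias, noise_cv=0.05)
factors = correction_factors(table, focal_pos=104, window=8)
raw, corrected = corrected_ratio(table, 104, factors)
result = classify_and_apportion(corrected, adjusted_copies=10_000.0)
print(f"raw T/(T+C) ratio:       {raw:.3f}   (biased by the 2:1 dye effect)")
print(f"corrected ratio:         {corrected:.3f}   (true alewife fraction 0.30)")
print(f"call: {result.call};  copies alewife/blueback = "
      f"{result.copies_alewife:.0f}/{result.copies_blueback:.0f}")
print()

fracs = [1 / 11, 1 / 5, 1 / 3, 1 / 2, 2 / 3, 4 / 5, 10 / 11]
tables = [simulate_chromatogram(p, rng=rng, bias=bias, noise_cv=0.10)
          for p in fracs]
res = mixture_validation(fracs, tables)
for kind in ("corrected", "raw"):
    r = res[kind]
    print(f"{kind:>9} estimator: slope={r.slope:.3f} intercept={r.intercept:.3f} "
          f"r2={r.r2:.3f}")
print()
print("The corrected estimator regresses on the known fractions with slope")
print("~1 and intercept ~0; the raw ratio is pushed toward the over-bright")
print("T allele, so its slope/intercept drift from the identity line.")
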