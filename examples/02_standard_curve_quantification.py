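"""Standard-curve quantification of a simulated qPCR plate.

Simulates one plate carrying three water samples of known copy number
(one clean, one PCR-inhibited, one blank), fits the per-plate standard
curve, applies the 2-of-3 detection rule at the Cq < 39 cutoff, flags
inhibition from the spiked 300,000-copy control, and standardizes copy
estimates to 1 L of filtered water.
"""

import numpy as np
import pandas as pd

from alosaedna import quantify
from alosaedna.simulate import simulate_plate

rng = np.random.default_rng(42)
truth = {"clean": 5_000.0, "muddy": 5_000.0, "blank": 0.0}
plate = simulate_plate(truth, rng=rng, noise_sigma=0.2,
                       inhibition={"muddy": 4.5})
samples = pd.DataFrame({"sample_id": list(truth),
                        "volume_ml": [800.0, 800.0, 800.0]})

quant, qc = quantify(plate, samples)
print("plate QC:")
print(qc[["plate_id", "passed", "slope", "intercept", "r2"]].round(4).to_string(index=False))
print()
cols = ["sample_id", "detected", "reaction_copies", "adjusted_copies",
        "inhibition_delta_cq", "inhibited"]
print(quant[cols].round(2).to_string(index=False))
print()
print("Both positive samples held ~5,000 true copies per reaction; the")
print("'muddy' extract shifts its spiked control by >= 3 cycles and is")
print("flagged inhibited (its copy estimate is biased low for the same")
print("reason).  adjusted_copies rescales to a 1 L sample: x 1000/800.")
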