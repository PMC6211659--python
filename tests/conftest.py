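import numpy as np
import pandas as pd
import pytest

from alosaedna.assay import RIVER_HERRING_OLIGOS
from alosaedna.simulate import synthetic_reference_set


@pytest.fixture(scope="session")
def refs():
    """The packaged synthetic CO1 reference panel."""
    return synthetic_reference_set()


@pytest.fixture(scope="session")
def oligos():
    return RIVER_HERRING_OLIGOS


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def perfect_plate():
    """Noise-free standards following Cq = 40 - 3.3219 log10(copies)."""
    rows = []
    for level in (300_000, 30_000, 3_000, 300, 30):
        for _ in range(2):
            rows.append({"plate_id": "p1", "well": "", "sample_id": f"std{level}",
                         "role": "standard", "known_copies": level,
                         "cq": 40.0 - 3.3219 * np.log10(level)})
    for _ in range(2):
        rows.append({"plate_id": "p1", "well": "", "sample_id": "blank",
                     "role": "standard", "known_copies": 0, "cq": np.nan})
    return pd.DataFrame(rows)


def uniform_peak_table(focal=104, window=10, height=1000.0, h_t=500.0, h_c=500.0):
    """Peak table with uniform called-base heights on the flanks and a
    T/C double peak at the focal position."""
    seq = "ACGTACGTACGTACGTACGTA"  # called bases cycle through all four
    rows = []
    for i, pos in enumerate(range(focal - window, focal + window + 1)):
        row = {"sample_id": "s", "position": pos,
               "height_A": 0.0, "height_C": 0.0, "height_G": 0.0, "height_T": 0.0}
        if pos == focal:
            row["called_base"] = "T" if h_t >= h_c else "C"
            row["height_T"] = h_t
            row["height_C"] = h_c
        else:
            b = seq[i % len(seq)]
            row["called_base"] = b
            row[f"height_{b}"] = height
        rows.append(row)
    return pd.DataFrame(rows)
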