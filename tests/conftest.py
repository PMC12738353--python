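import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from isomirdiv.diversity import IsomirCountTable
from isomirdiv.io import COUNT_KEY_COLUMNS, load_mir455_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mir455():
    """(precursor_id, precursor sequence, mature annotation) of the shipped
    miR-455 hairpin fixture."""
    return load_mir455_fixture()


# ---------------------------------------------------------------------------
# A 5-miRNA x 6-sample count table small enough to follow by hand.
# Samples: 4 tumors (T1, T2 favorable; T3, T4 unfavorable) and 2 normals.
# Expected values for every stage were computed by hand and are asserted
# against in the tests that use this fixture:
#   filter (>100 in >=1 sample): drops (mB,0,2) max=50 and (mC,0,0) max=100
#   diversity (count >= 1):  mA (3,2,1,1,4,4)   mB (2,2,2,2,1,2)
#                            mD (1,0,0,0,0,0)   mE (3,3,2,2,3,3)
#   medians: mA 2.5, mB 2, mD 0, mE 3  -> eligible at min_median=3: [mE]
#   pooled categories (tumor): mA 3, mB 2, mD 1, mE 3 -> (1, 3, 0)
#   pooled categories (normal): mA 4, mB 2, mE 3 (mD unobserved) -> (0, 3, 0)
#   Welch on mE tumor (3,3,2,2) vs normal (3,3): t = -1.7320508,
#   df = 3, p = 0.18169011, FC = 2.5/3
# ---------------------------------------------------------------------------
HAND_ROWS = [
    ("mA", 0, 0, [500, 400, 300, 200, 600, 700]),
    ("mA", 0, 1, [150, 120, 0, 0, 300, 250]),
    ("mA", 0, -1, [101, 0, 0, 0, 200, 150]),
    ("mA", 1, 0, [0, 0, 0, 0, 120, 130]),
    ("mB", 0, 0, [1000, 900, 800, 700, 100, 100]),
    ("mB", 0, 1, [300, 200, 150, 120, 0, 101]),
    ("mB", 0, 2, [50, 40, 30, 20, 10, 5]),
    ("mC", 0, 0, [100, 90, 80, 100, 100, 100]),
    ("mD", 0, 0, [101, 0, 0, 0, 0, 0]),
    ("mE", 0, 0, [120, 130, 140, 150, 160, 170]),
    ("mE", 0, 1, [110, 115, 0, 125, 135, 145]),
    ("mE", -1, 0, [105, 150, 160, 0, 180, 190]),
]
HAND_SAMPLES = ["T1", "T2", "T3", "T4", "N1", "N2"]


@pytest.fixture()
def hand_table() -> IsomirCountTable:
    index = pd.MultiIndex.from_tuples(
        [(m, o5, o3) for m, o5, o3, _ in HAND_ROWS], names=COUNT_KEY_COLUMNS
    )
    counts = pd.DataFrame(
        [row for *_, row in HAND_ROWS], index=index, columns=HAND_SAMPLES
    )
    samples = pd.DataFrame(
        {
            "tissue": ["tumor"] * 4 + ["normal"] * 2,
            "histology": ["favorable", "favorable", "unfavorable", "unfavorable", "NA", "NA"],
            "gender": ["male", "female", "male", "female", "male", "female"],
        },
        index=pd.Index(HAND_SAMPLES, name="sample_id"),
    )
    return IsomirCountTable(counts, samples)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
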