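import numpy as np
import pytest

from lesiongan.phantom import generate_phantom_case
from lesiongan.preprocessing import SemanticLabel
from lesiongan.training import SliceDataset


@pytest.fixture(scope="session")
def phantom_case():
    return generate_phantom_case(7, (8, 64, 64), ["flair", "t1ce"])


@pytest.fixture(scope="session")
def flair_cases():
    return [generate_phantom_case(1000 + i, (8, 64, 64), ["flair"]) for i in range(4)]


@pytest.fixture(scope="session")
def flair_dataset(flair_cases):
    return SliceDataset(flair_cases, "flair", 64)


def make_label(classes, patient="p", idx=0):
    return SemanticLabel(classes=np.asarray(classes), patient_id=patient, slice_index=idx)


@pytest.fixture
def toy_labels():
    """6x6 donor pair with overlapping tumors for hand-checked mask tests."""
    s_a = np.zeros((6, 6), dtype=int)
    s_a[1:5, 1:5] = 1          # brain of A
    s_a[2:4, 2:4] = 2          # A's tumor (edema)
    s_a[2, 2] = 4
    s_b = np.zeros((6, 6), dtype=int)
    s_b[0:5, 0:5] = 1          # brain of B, offset from A's
    s_b[3:5, 3:5] = 3          # B's tumor (core)
    return make_label(s_a, "A"), make_label(s_b, "B")
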