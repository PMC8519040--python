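from pathlib import Path

import pytest
from hypothesis import settings

import isomilk as im

settings.register_profile("derandomized", derandomize=True, max_examples=100)
settings.load_profile("derandomized")

REPO_ROOT = Path(__file__).resolve().parents[1]
VALIDATION_CSV = REPO_ROOT / "examples" / "data" / "validation_samples.csv"

# Validation herd expectations: for each sample, the published computed
# columns at printed precision — calculated milk δ¹⁸O (2 dp), step-1
# 10³Δ (2 dp), measured α (6 dp), predicted α̂ (6 dp), step-2 10³Δ (2 dp) —
# and the two-step verdict.
VALIDATION_EXPECTED = [
    # (shed, t, delta_calc, d1, alpha_m, alpha_hat, d2, overall)
    ("Torrile", 20, -8.11, 0.05, 1.000625, 1.001036, 0.41, True),
    ("Torrile", 56, -8.02, 0.47, 1.001322, 1.001224, 0.10, True),
    ("Villa Minozzo", 36, -8.13, 0.32, 1.001302, 1.001058, 0.24, True),
    ("Quattro Castella", 36, -8.13, 0.21, 1.000858, 1.001058, 0.20, True),
    ("Viarolo", 358, -8.21, 1.46, 1.000766, 1.001096, 0.33, True),
    ("L1", 220, -6.43, 0.47, 1.002959, 1.002692, 0.27, True),
    ("L2", 150, -6.79, 0.47, 1.001584, 1.002534, 0.95, False),
    ("L3", 182, -6.50, 0.23, 1.001432, 1.002747, 1.32, False),
    ("L4", 30, -8.14, 0.94, 1.002140, 1.001036, 1.10, False),
]


@pytest.fixture(scope="session")
def eq5():
    return im.load_calibration("eq5_milk_d18O")


@pytest.fixture(scope="session")
def eq6a():
    return im.load_calibration("eq6a_alpha_all")


@pytest.fixture(scope="session")
def eq6b():
    return im.load_calibration("eq6b_alpha_indoor")


@pytest.fixture(scope="session")
def validation_records():
    result = im.read_samples(str(VALIDATION_CSV))
    assert not result.errors
    return result.records
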