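"""Shared fixtures: one synthetic block family and its calibrated profiles.

Everything is generated programmatically at fixed seeds; building and
calibrating the ten block profiles takes ~2 s once per session.
"""
import numpy as np
import pytest

from dscamscan.msa_blocks import extract_blocks
from dscamscan.phmm import build_profile, calibrate
from dscamscan.synthetic_data import make_block_family

N_BLOCKS = 10
BLOCK_MIN, BLOCK_MAX = 25, 50
CAL_N, CAL_LEN = 1000, 100


@pytest.fixture(scope="session")
def family():
    return make_block_family(seed=0)


@pytest.fixture(scope="session")
def blocks(family):
    out = extract_blocks(family.alignment, N_BLOCKS, BLOCK_MIN, BLOCK_MAX)
    assert len(out) == N_BLOCKS
    return out


@pytest.fixture(scope="session")
def hmms(blocks):
    return [calibrate(build_profile(b), CAL_N, CAL_LEN, seed=i)
            for i, b in enumerate(blocks)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
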