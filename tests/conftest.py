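"""Shared fixtures: representative stimuli at full and reduced geometry.

Session-scoped because stimulus generation and convolution are the expensive
steps; all tests treat the fixture images as read-only.
"""

import numpy as np
import pytest

from ltbseg import LTBSpec, LSBSpec, make_lsb, make_ltb


@pytest.fixture(scope="session")
def ltb_default():
    """Full-size texture boundary at the standard study conditions."""
    return make_ltb(LTBSpec(n_p=32, pi_U=0.5, A=0.25, seed=1))


@pytest.fixture(scope="session")
def ltb_small():
    """Reduced geometry used where full-size stimuli would be wasteful."""
    return make_ltb(LTBSpec(n_p=16, pi_U=0.5, A=0.25, image_size=128,
                            taper_width=8.0, seed=1))


@pytest.fixture(scope="session")
def lsb_default():
    return make_lsb(LSBSpec(c_M=0.02, orientation="right_oblique", phase=0))


@pytest.fixture(scope="session")
def uniform_disc():
    """Mid-gray disc: a zero-contrast stimulus."""
    return make_lsb(LSBSpec(c_M=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
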