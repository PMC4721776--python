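"""Shared fixtures: synthetic identities and captures (session-scoped)."""

import numpy as np
import pytest

from palmfuse import synth_hands as sh

MASTER_SEED = 42


@pytest.fixture(scope="session")
def identity():
    """First identity of the master-seed-42 cohort."""
    return sh.make_identity(MASTER_SEED, 0)


@pytest.fixture(scope="session")
def second_identity():
    return sh.make_identity(MASTER_SEED, 1)


@pytest.fixture(scope="session")
def palm_capture(identity):
    """Zero-jitter palm capture (seed 7) with ground truth."""
    return sh.generate_palm_image(identity, sh.CaptureJitter(), seed=7)


@pytest.fixture(scope="session")
def noiseless_palm(identity):
    return sh.generate_palm_image(identity, sh.CaptureJitter(noise_sigma=0), seed=7)


@pytest.fixture(scope="session")
def dorsum_capture(identity):
    """Zero-jitter dorsum capture (seed 7) with ground truth."""
    return sh.generate_dorsum_image(identity, sh.CaptureJitter(noise_sigma=1.5), seed=7)


@pytest.fixture(scope="session")
def palm_roi(palm_capture):
    from palmfuse.roi_locator import extract_roi

    return extract_roi(palm_capture[0], "palm")


@pytest.fixture(scope="session")
def dorsum_roi(dorsum_capture):
    from palmfuse.roi_locator import extract_roi

    return extract_roi(dorsum_capture[0], "dorsum")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
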