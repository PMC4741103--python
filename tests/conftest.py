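"""Shared fixtures: small synthetic sessions and trained states.

Everything is generated programmatically with fixed seeds; the expensive
12-avatar benchmark run is module-scoped inside test_acceptance.py so the
unit tests here stay fast.
"""

import numpy as np
import pytest

from imitrec import Config, default_avatar_specs, generate_session, subsample_session


@pytest.fixture(scope="session")
def specs12():
    return default_avatar_specs()


@pytest.fixture(scope="session")
def small_cfg():
    return Config(n_avatars=3, frames_per_partner=100)


@pytest.fixture(scope="session")
def small_session(specs12, small_cfg):
    """Three avatars, 100 frames each: enough structure for unit tests."""
    return generate_session(specs12[:3], small_cfg.frames_per_partner,
                            posture_schedule_seed=11,
                            noise_level=small_cfg.noise_level)


@pytest.fixture(scope="session")
def small_learning(small_session):
    return subsample_session(small_session, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
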