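"""Shared fixtures: small phantoms and hospital profiles."""

import numpy as np
import pytest

from fedmammo import HospitalProfile, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def plain_profile():
    return HospitalProfile("H1", intensity_range=(0.0, 4095.0))


@pytest.fixture(scope="session")
def artifact_profile():
    return HospitalProfile(
        "H1",
        intensity_range=(0.0, 4095.0),
        label_prob=1.0,
        clip_prob=1.0,
    )


@pytest.fixture(scope="session")
def inverted_profile():
    return HospitalProfile(
        "H2", intensity_range=(3000.0, 4095.0), photometric="MONOCHROME1"
    )


@pytest.fixture(scope="session")
def labeled_phantom(artifact_profile):
    """A 128x128 left-breast phantom guaranteed to carry a printed label."""
    rec = generate_phantom(
        PhantomSpec(image_size=(128, 128), laterality="L", birads=3, seed=42),
        artifact_profile,
    )
    assert rec.artifacts.has_label
    return rec


@pytest.fixture(scope="session")
def plain_phantom(plain_profile):
    return generate_phantom(
        PhantomSpec(image_size=(128, 128), laterality="L", birads=2, seed=7),
        plain_profile,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
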