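import numpy as np
import pytest

from nodugrade import patches, synthetic


@pytest.fixture(scope="session")
def spiky_phantom():
    params = synthetic.SCGenParams(
        spiculation_level=4, lobulation_level=3, sphericity_level=4,
        margin_level=4, subtlety_level=4, calcification_level=3, seed=42,
    )
    return synthetic.generate_nodule_phantom(params, case_id="fixture")


@pytest.fixture(scope="session")
def fixture_patch(spiky_phantom):
    """Deterministic 64x64 G/B patch used across feature tests."""
    return patches.patches_from_case(spiky_phantom)[0]


@pytest.fixture(scope="session")
def small_cohort():
    cases, table = synthetic.generate_cohort(30, seed=5)
    return cases, table


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
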