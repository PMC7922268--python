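import numpy as np
import pytest

from kneegap.cohort import KneeParams, generate_knee


@pytest.fixture(scope="session")
def symmetric_knee():
    """Fully symmetric noise-free knee: no deformity, no wear, no asymmetry."""
    return generate_knee(KneeParams(side="right"), knee_id="symmetric")


@pytest.fixture(scope="session")
def varus_knee():
    """Representative varus knee with medial wear and anatomical asymmetries."""
    return generate_knee(
        KneeParams(
            side="right",
            hka_deg=8.2,
            distal_asym=1.2,
            posterior_asym=1.5,
            tea_rotation_deg=2.0,
            trochlea_rotation_deg=-1.5,
            wear_fem_med=2.0,
            wear_tib_med=1.5,
            wear_fem_lat=0.2,
            wear_tib_lat=0.1,
            tibial_slope_deg=3.0,
            seed=7,
        ),
        knee_id="varus_example",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
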