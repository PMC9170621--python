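import math

import numpy as np
import pytest

from cvdscreen import Axis, ChromaticityMB, DeviceProfile, EngineConfig


@pytest.fixture(scope="session")
def default_profile() -> DeviceProfile:
    return DeviceProfile.default()


@pytest.fixture(scope="session")
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def simple_profile() -> DeviceProfile:
    """Hand-built profile with easy geometry for gamut/transform oracles.

    Primaries are axis-aligned-ish in cone space, gamma is 1 (linear),
    the background sits mid-gamut, and the endpoints are placed along
    valid confusion-line directions (tritan endpoint shares the
    background l).
    """
    white = ChromaticityMB(l=0.65, s=0.02, lum=0.5)
    return DeviceProfile(
        model_id="unit-test-linear",
        rgb_to_lms=np.array(
            [
                [0.60, 0.35, 0.05],
                [0.10, 0.85, 0.05],
                [0.00, 0.02, 0.98],
            ]
        ),
        gamma=np.array([1.0, 1.0, 1.0]),
        white=white,
        axis_endpoints={
            Axis.PROTAN: ChromaticityMB(0.60, 0.025),
            Axis.DEUTAN: ChromaticityMB(0.61, 0.022),
            Axis.TRITAN: ChromaticityMB(0.65, 0.004),
        },
    )
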