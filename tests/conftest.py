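"""Shared fixtures: a fast optical configuration and cached models.

The fast configuration (64 pupil samples, 2x oversampling) is accurate
to well below the tolerances asserted anywhere in the suite while
keeping model builds and fits quick.
"""

import numpy as np
import pytest

from rimap.optics import (EmitterState, LayeredSample, MoleculeImageModel,
                          OpticalSystem)


@pytest.fixture(scope="session")
def fast_system():
    return OpticalSystem(oversampling=2, pupil_samples=64)


@pytest.fixture(scope="session")
def accurate_system():
    return OpticalSystem()  # 96 pupil samples, 3x oversampling


@pytest.fixture(scope="session")
def layer_100():
    return LayeredSample(n_layer=1.43, thickness=100.0)


@pytest.fixture(scope="session")
def glass():
    return LayeredSample(n_layer=1.33, thickness=0.0)


@pytest.fixture(scope="session")
def model_cache():
    """Session-wide cache of MoleculeImageModel builds."""
    cache = {}

    def get(system, sample, precision="double"):
        key = (repr(system), repr(sample), precision)
        if key not in cache:
            cache[key] = MoleculeImageModel(system, sample,
                                            precision=precision)
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def crest_emitter():
    return EmitterState(axial_position=100.0, signal_photons=5000.0,
                        background_per_pixel=20.0)
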