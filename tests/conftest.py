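"""Shared small-scale fixtures: a reduced helmet, cortex, and amygdala model.

Everything is generated programmatically at collection time; sizes are kept
small so the whole suite runs quickly while exercising the same code paths
as the full-scale configuration.
"""

import numpy as np
import pytest

from deepmeg import anatomy, forward, pipeline


@pytest.fixture(scope="session")
def small_geometry() -> pipeline.GeometryConfig:
    return pipeline.GeometryConfig(
        n_channels=48,
        cortex_vertices=400,
        amygdala_spacing=0.003,
        hippocampus_vertices=60,
    )


@pytest.fixture(scope="session")
def small_model(small_geometry) -> pipeline.SourceModel:
    return pipeline.build_source_model(small_geometry, patch_vertices=12)


@pytest.fixture(scope="session")
def small_sensors(small_model) -> anatomy.SensorArray:
    return small_model.sensors


@pytest.fixture(scope="session")
def small_head_model(small_model) -> anatomy.HeadModel:
    return small_model.head_model


@pytest.fixture(scope="session")
def small_gain(small_model) -> forward.GainMatrix:
    return small_model.gain


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
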