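import numpy as np
import pytest

from seedlingcounter.synthetic import FieldConfig, generate_dataset, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(FieldConfig(image_size=96, n_rows=3, plants_per_row=4,
                                      seed=7, min_box_side=6))


@pytest.fixture(scope="session")
def scene_batch():
    cfg = FieldConfig(image_size=96, n_rows=3, plants_per_row=4, seed=21, min_box_side=6)
    return generate_dataset(8, cfg)
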