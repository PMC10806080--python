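import numpy as np
import pytest

from chipcnn.chipsim import GeneratorParams, generate_dataset
from chipcnn.preprocess import build_inputs, split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_params():
    """A cheap generator configuration for unit tests."""
    return GeneratorParams(roi_height_px=48, roi_width_px=48,
                           n_rois_per_chip=4, n_slices=5, seed=7)


@pytest.fixture(scope="session")
def tiny_split(small_params):
    """A small but complete train/val/test split (2 chips per level)."""
    _, chips = generate_dataset(small_params, chips_per_level=2,
                                level0_missing_rois=0, seed=7)
    inputs = build_inputs(chips, (1, 3, 5))
    return split_dataset(inputs, val_fraction=0.10, seed=7)
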