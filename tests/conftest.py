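import numpy as np
import pytest

from orchardvit.synthetic import (
    DatasetDesign,
    generate_dataset,
    load_dataset_arrays,
    variety_specs,
)

TINY_IMAGE = 12  # one 2x2 grid of 6x6 patches — fastest geometry that still attends


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """3 easy hue-separated classes, 8 train / 4 test each, 12x12 px."""
    d = tmp_path_factory.mktemp("tinyds")
    design = DatasetDesign("tiny3", ["a", "b", "c"], 8, 4, image_size=TINY_IMAGE)
    specs = variety_specs(design.classes, clutter=0.1, noise_sd=0.01)
    generate_dataset(design, specs, d, master_seed=11, overwrite=True)
    return d


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset_dir):
    X, y, names = load_dataset_arrays(tiny_dataset_dir, "train")
    Xt, yt, _ = load_dataset_arrays(tiny_dataset_dir, "test")
    return X, y, Xt, yt, names


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
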