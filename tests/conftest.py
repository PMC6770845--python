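import numpy as np
import pytest

from ccens import models, preprocess, simdata, training


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_arch():
    """32x32 architecture with minimal widths, for fast training tests."""
    return models.ArchitectureConfig(input_height=32, input_width=32,
                                     unet_depth=2, unet_base_filters=4,
                                     ae_filters=(4, 4, 4),
                                     tail_filters=(4, 4, 8, 8),
                                     tail_dense_units=16, seed=7)


@pytest.fixture(scope="session")
def tiny_corpus():
    """32 harmonized 32x32 scenes with low counts and both annotations."""
    cfg = simdata.preset_config(
        "dot", height=32, width=32, seed=5,
        count_law=simdata.DistSpec("uniform_int", low=1, high=10),
        cell_radius_law=simdata.DistSpec("uniform", low=1.5, high=3.0))
    ds = simdata.generate_dataset(cfg, 32, seed=5)
    spec = preprocess.PreprocessSpec(target_height=32, target_width=32)
    return preprocess.harmonize(ds, spec)


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    """A DatasetSplit built from two small corpora sharing one shape."""
    cfg = simdata.preset_config(
        "mask", height=32, width=32, seed=9,
        count_law=simdata.DistSpec("uniform_int", low=1, high=10),
        cell_radius_law=simdata.DistSpec("uniform", low=1.5, high=3.0))
    mask_ds = simdata.generate_dataset(cfg, 24, seed=9)
    spec = preprocess.PreprocessSpec(target_height=32, target_width=32)
    mask_ds = preprocess.harmonize(mask_ds, spec)
    return training.make_split(tiny_corpus, mask_ds, n_test_each=6, seed=3)
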