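import numpy as np
import pytest

from vht_smear.features import VHTFeatureExtractor
from vht_smear.synth import CLASSES, GeneratorConfig, render_cell


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_image_set(gen_cfg):
    """12 rendered smears per class, shared across tests."""
    images = {lab: [render_cell(lab, gen_cfg, np.random.default_rng([0, ci, i]))
                    for i in range(12)]
              for ci, lab in enumerate(CLASSES)}
    return images


@pytest.fixture(scope="session")
def small_feature_set(small_image_set):
    """VHT feature matrix and labels for the shared image set."""
    ex = VHTFeatureExtractor()
    X, y = [], []
    for lab, imgs in small_image_set.items():
        for im in imgs:
            X.append(ex.transform_image(im).values)
            y.append(lab)
    return np.array(X), np.array(y)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory, gen_cfg):
    """A 4-image-per-class dataset on disk with its manifest."""
    from vht_smear.synth import generate_dataset

    root = tmp_path_factory.mktemp("smears")
    manifest = generate_dataset(4, gen_cfg, root)
    return root, manifest
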