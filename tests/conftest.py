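import numpy as np
import pytest

import privgrad as pg
from privgrad import nn


@pytest.fixture(scope="session")
def cls_dataset(tmp_path_factory):
    """Small synthetic classification fixture: 150 negative / 350 positive,
    32x32, split 85/15 — the desk-scale analogue of the imbalanced
    chest-film task."""
    out = tmp_path_factory.mktemp("cls_data")
    spec = pg.GeneratorSpec(task="classification", image_size=32,
                            class_counts=(150, 350), seed=7)
    manifest = pg.generate_classification(spec, out)
    return manifest


@pytest.fixture(scope="session")
def seg_dataset(tmp_path_factory):
    """Small synthetic segmentation fixture: 96 image/mask pairs at 32x32
    with subject-grouped splits."""
    out = tmp_path_factory.mktemp("seg_data")
    spec = pg.GeneratorSpec(task="segmentation", image_size=32, n_images=96,
                            subjects_per=4, seed=11)
    return pg.generate_segmentation(spec, out)


def random_cnn(seed: int, image_size: int = 16, width: int = 4) -> nn.Sequential:
    return pg.tiny_cnn(image_size, width=width, seed=seed)


def ce_loss(labels):
    """Per-sample cross-entropy closure in the engine's signature."""
    def loss_fn(out, within):
        return nn.softmax_cross_entropy(out, labels[within], None)
    return loss_fn
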