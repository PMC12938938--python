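"""Shared fixtures: small network specs and synthetic datasets.

Networks in tests use a narrow filter schedule and a small input side so whole
pipelines run in seconds; the architecture arithmetic (patchify stem, doubling
downsamples, GAP head) is identical to the full-size default."""

import numpy as np
import pytest

from exemplarnet import ArchitectureSpec, build_model
from exemplarnet.synthetic import SyntheticImageSpec, generate_image_dataset

SMALL_FILTERS = (8, 16, 32, 64, 48)


@pytest.fixture(scope="session")
def small_spec():
    return ArchitectureSpec(filters=SMALL_FILTERS, input_side=32, num_classes=3)


@pytest.fixture(scope="session")
def small_model(small_spec):
    return build_model(small_spec, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """3-class, 32-px synthetic image dataset with both global and local signal."""
    root = tmp_path_factory.mktemp("tinyset")
    spec = SyntheticImageSpec(n_classes=3, train_per_class=12, test_per_class=4,
                              image_side=32, seed=42)
    generate_image_dataset(spec, root)
    return root
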