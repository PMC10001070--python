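import numpy as np
import pytest

from aquilens.datasets import (DatasetProfile, builtin_profiles,
                               generate_dataset)


@pytest.fixture(scope="session")
def two_class_profile():
    """Small 2-class profile with the built-in dataset1 textures."""
    base = builtin_profiles()["dataset1"]

    def make(n_per_class=50, separability=1.0, size=(64, 64)):
        return DatasetProfile(
            name="toy2",
            class_names=("benign", "malignant"),
            class_counts={"benign": n_per_class, "malignant": n_per_class},
            image_size=size,
            texture_params=base.texture_params,
            separability=separability,
        )

    return make


@pytest.fixture(scope="session")
def separable_data(two_class_profile):
    """100 fully separable images, shared across tests (read-only)."""
    return generate_dataset(two_class_profile(50, 1.0), seed=7)


@pytest.fixture(scope="session")
def separable_features(separable_data):
    from aquilens.squeezenet import build_network, extract_features

    model = build_network(seed=0)
    model.calibrate_batchnorm(
        np.asarray(separable_data.images[:32], dtype=float) / 255.0)
    return model, extract_features(model, separable_data)
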