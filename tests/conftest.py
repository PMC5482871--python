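import numpy as np
import pytest

from hiercls.data_io import patient_wise_split
from hiercls.hierarchy import default_breakhis_taxonomy
from hiercls.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def taxonomy():
    return default_breakhis_taxonomy()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Tiny synthetic dataset shared across tests: 8 subclasses x 3 patients
    x 4 images at 32x32, split patient-wise."""
    out = tmp_path_factory.mktemp("smalldata")
    cfg = SyntheticConfig(
        patients_per_subclass=3, images_per_patient=4, image_size=32, rng_seed=11
    )
    manifest = generate_dataset(cfg, out)
    return patient_wise_split(manifest, rng_seed=11), cfg


def random_unit_vectors(rng, n, d):
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
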