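import numpy as np
import pandas as pd
import pytest

from molarmorph.landmark_io import LandmarkConfiguration
from molarmorph.synthetic_data import SynthSpec, generate, make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160511)


def random_shape(rng, k=15, spread=1.0):
    """Non-degenerate random landmark configuration."""
    while True:
        x = rng.normal(scale=spread, size=(k, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        if d[~np.eye(k, dtype=bool)].min() > 1e-3:
            return x


def three_family_counts(n_per_group=20):
    return pd.DataFrame(
        {
            "genus": ["GenA", "GenB", "GenC"],
            "species": ["GenA sp", "GenB sp", "GenC sp"],
            "n": [n_per_group] * 3,
            "subfamily_G": ["Cebinae", "Pitheciinae", "Atelinae"],
            "subfamily_R": ["Cebinae", "Pitheciinae", "Atelinae"],
            "family": ["Cebidae", "Pitheciidae", "Atelidae"],
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Three-family synthetic dataset with clear group structure (+fossils)."""
    spec = SynthSpec(
        taxonomy_counts=three_family_counts(20),
        group_effect=0.5,
        within_sigma=0.06,
        n_fossils=2,
        seed=7,
    )
    return generate(spec)


def as_config(landmarks, specimen_id="s", tooth="M1", side="right", scale=1.0):
    return LandmarkConfiguration(
        specimen_id=specimen_id, tooth=tooth, side=side,
        landmarks=np.asarray(landmarks, float), scale=scale,
    )
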