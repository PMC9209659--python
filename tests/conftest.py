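import dataclasses

import numpy as np
import pytest

from methsub.simulate import SynthConfig, generate_cohort
from methsub.types import SubtypeAssignment


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale cohort: 4 subtypes x 30 tumors, 10 normals, 2000 probes
    with 200 planted differential probes (40 of them subtype-specific)."""
    return SynthConfig(
        k_subtypes=4, n_per_subtype=30, n_normal=10,
        n_probes=2000, n_diff_probes=200, n_specific_per_subtype=10,
        n_genes=400, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def imputed_cohort(small_cfg):
    """Same layout without injected missingness (usable pre-imputation)."""
    return generate_cohort(dataclasses.replace(small_cfg, missing_frac=0.0, seed=12))


@pytest.fixture(scope="session")
def true_labels(imputed_cohort):
    return SubtypeAssignment(dict(imputed_cohort.truth.subtype_of))


@pytest.fixture()
def blobs():
    """Four perfectly separated Gaussian blobs (20 samples each)."""
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [40, 0], [0, 40], [40, 40]], dtype=float)
    X = np.concatenate([c + rng.normal(0, 0.5, size=(20, 2)) for c in centers])
    labels = np.repeat(np.arange(1, 5), 20)
    return X, labels
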