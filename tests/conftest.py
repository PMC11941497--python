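import numpy as np
import pytest

import epidermap as em
from epidermap.datatypes import TissueParams


@pytest.fixture(scope="session")
def default_dataset():
    """Fully patterned homeostatic section, default conditions."""
    return em.generate_dataset(n=2000, pattern_strength=1.0, seed=1)


@pytest.fixture(scope="session")
def analyzed(default_dataset):
    """Pipeline result on the default section (covariates, gating, clusters)."""
    return em.analyze_dataset(default_dataset, seed=1)


@pytest.fixture(scope="session")
def sparse_dataset():
    """Well-separated nuclei on a follicle-free strip, render-friendly."""
    params = TissueParams(section_length=1500.0, hf_positions=(), pixel_size=0.5)
    ann = em.generate_tissue_geometry(params)
    return em.generate_nuclei(
        ann, em.default_archetypes(), n=50, pattern_strength=0.0, seed=7,
        params=params, min_separation=16.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
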