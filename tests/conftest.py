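import numpy as np
import pytest

import halfscsa as h
from halfscsa.similarity import initial_references, optimize_references


@pytest.fixture(scope="session")
def small_plant():
    """A reduced 2-phytomer plant with noise and outliers, plus its HALF
    field and optimized references (shared: the field dominates runtime)."""
    spec = h.PlantSpec(
        n_phytomers=2, leaf_density=0.7, stem_density=12.0, rng_seed=11
    )
    noise = h.NoiseModel(sigma0=0.1, outlier_fraction=0.05)
    cloud, truth = h.make_plant(spec, noise)
    params = h.HalfParams(n_pairs=8000, rng_seed=11)
    field = h.compute_half_field(cloud, params)
    refs = optimize_references(field, initial_references())
    return {
        "spec": spec,
        "cloud": cloud,
        "truth": truth,
        "params": params,
        "field": field,
        "refs": refs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
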