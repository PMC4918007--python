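import numpy as np
import pandas as pd
import pytest

from sulfidiv import synthetic


@pytest.fixture(scope="session")
def small_design():
    return synthetic.StudyDesign(
        n_clades=2, systems_per_clade=2, nonsulfidic_per_system=1
    )


@pytest.fixture(scope="session")
def small_sites(small_design):
    return synthetic.generate_sites(small_design, seed=42)


@pytest.fixture(scope="session")
def small_traits(small_sites):
    return synthetic.generate_traits(small_sites, n_per_site=16, seed=42)


@pytest.fixture(scope="session")
def small_shapes(small_sites):
    return synthetic.generate_landmarks(small_sites, n_per_site=16, seed=42)


@pytest.fixture(scope="session")
def small_genotypes(small_sites):
    effects = synthetic.EffectConfig(divergence_F=0.2, scale_F_with_h2s=False)
    return synthetic.generate_genotypes(
        small_sites, effects, n_per_site=20, n_loci=8, seed=42
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def two_group_frame(rng):
    """Two habitat groups differing in the first of three responses."""
    n = 200
    sulfidic = np.repeat([True, False], n // 2)
    y1 = rng.normal(0, 1, n) + 2.0 * sulfidic
    y2 = rng.normal(0, 1, n)
    y3 = rng.normal(0, 1, n)
    return pd.DataFrame({"sulfidic": sulfidic, "y1": y1, "y2": y2, "y3": y3})
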