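import numpy as np
import pytest

from mcfrw.geometry import (PerturbationConfig, build_lattice, perturb)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced fibril (R = 30 nm, L = 300 nm) for brute-force comparisons."""
    geom = build_lattice(rng=1, envelope_radius=30.0, envelope_length=300.0)
    return perturb(geom, PerturbationConfig(n_moves=100_000, rng_seed=3))


@pytest.fixture(scope="session")
def default_fibril():
    """Full default fibril model: built lattice plus the 6e6-move perturbation."""
    geom = build_lattice(rng=0)
    return perturb(geom, PerturbationConfig(n_moves=6_000_000, rng_seed=7))
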