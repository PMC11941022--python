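import numpy as np
import pytest

import amorphmob as am


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def small_mixed_frame(rng):
    """68 lactose + 32 water at uniform-random positions in a reference box."""
    cell = am.build_cell(0.11)
    pos = rng.uniform(0, cell.box_side, size=(100, 3))
    species = np.array(["lactose"] * 68 + ["water"] * 32, dtype=object)
    return am.Frame(time=0.0, positions=pos, species=species,
                    box_side=cell.box_side)


@pytest.fixture
def tiny_trajectory(rng):
    """3 water + 2 lactose over five frames, small diffusive moves."""
    n, L = 5, 30.0
    species = np.array(["water"] * 3 + ["lactose"] * 2, dtype=object)
    pos = np.empty((5, n, 3))
    pos[0] = rng.uniform(5, 25, size=(n, 3))
    for k in range(1, 5):
        pos[k] = pos[k - 1] + rng.normal(scale=0.3, size=(n, 3))
    return am.trajectory_from_array(np.arange(5.0), pos % L, species, L,
                                    dt_record=1.0)


@pytest.fixture(scope="session")
def clustering_reference_trajectory():
    """Seeded two-phase fixture: compact start, free expansion to 20 ps,
    centroid-directed contraction afterwards (1000 molecules)."""
    cell = am.build_cell(0.33, n_total=1000)
    dyn = am.DynamicsParams(init_spread=2.0)  # kappa_cluster 0.05 default
    return am.simulate(cell, dyn, temperature=303.0, seed=12345)
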