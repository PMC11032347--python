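"""Shared fixtures: toy complexes and detected cavities.

Cavity detection is the expensive step, so detection products are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from ppi_pocketome import (
    CavityParams,
    ToyComplexSpec,
    build_grid,
    detect_pockets,
    make_toy_heterodimer,
)
from ppi_pocketome.cavities import buriedness_many


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(seed=1)


@pytest.fixture(scope="session")
def heterodimer(toy_spec):
    return make_toy_heterodimer(toy_spec)


@pytest.fixture(scope="session")
def hd_grid(heterodimer):
    """Scored candidate grid for chain A with chain B as reference."""
    params = CavityParams()
    grid = build_grid(heterodimer.chain("A"),
                      heterodimer.chain("B").heavy_atoms(), params)
    return buriedness_many(grid, heterodimer.chain("A"))


@pytest.fixture(scope="session")
def hd_cavities(heterodimer):
    return detect_pockets(heterodimer.chain("A"),
                          heterodimer.chain("B").heavy_atoms())


@pytest.fixture(scope="session")
def hd_cavity(hd_cavities):
    assert hd_cavities, "toy heterodimer must yield at least one cavity"
    return hd_cavities[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cavity(rng, n_points=40, step=1.0):
    """A synthetic cavity with random lattice coords, burial and probes."""
    from ppi_pocketome.models import Cavity, GridPoint, PROBE_TYPES

    seen = set()
    while len(seen) < n_points:
        seen.add(tuple(rng.integers(-8, 9, size=3)))
    points = [
        GridPoint(
            coords=np.array(idx, dtype=float) * step,
            buriedness=int(rng.integers(0, 121)),
            probe=PROBE_TYPES[rng.integers(0, len(PROBE_TYPES))],
        )
        for idx in sorted(seen)
    ]
    return Cavity(cavity_id="CAVITY_N1", points=points, step=step)
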