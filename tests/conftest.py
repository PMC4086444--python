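import warnings

import numpy as np
import pytest

import geodeid as gd


@pytest.fixture
def grid_city() -> gd.LocationTable:
    """5x5 grid of areas ~1.1 km apart, mixed populations, deterministic."""
    rng = np.random.default_rng(42)
    lat, lon, pop = [], [], []
    for r in range(5):
        for c in range(5):
            lat.append(45.40 + 0.01 * r)
            lon.append(-75.70 + 0.01 * c)
            pop.append(int(rng.integers(1, 40)))
    return gd.LocationTable(
        area_ids=tuple(f"G{r}" for r in range(25)),
        lat=np.array(lat),
        lon=np.array(lon),
        population=np.array(pop),
    )


@pytest.fixture
def tiny_city() -> gd.LocationTable:
    """Four areas on a rough line with distinct populations."""
    return gd.LocationTable(
        area_ids=("a", "b", "c", "d"),
        lat=np.array([45.0, 45.01, 45.03, 45.07]),
        lon=np.array([-75.5, -75.5, -75.5, -75.5]),
        population=np.array([5, 50, 12, 200]),
    )


def make_problem(city, s, epsilon, variant, k=None):
    k = len(city) if k is None else k
    nb = gd.nearest_neighbors(city, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gd.DeidProblem(city, nb, s, epsilon, variant)
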