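"""Synthetic cities with the small-area structure of urban postal geography.

Real urban postal geographies (the kind this library targets) consist of
thousands of tiny areal units — a median of around 10 residents — with a
long right tail of larger units, so that the vast majority of areas hold
fewer people than a typical patient cohort.  That small-area structure is
what breaks worst-case re-identification bounds, and the generator is
built to exhibit it faithfully:

* **Urban core.**  Most areas sit in a dense central zone with log-normal
  populations (σ = 1.3, long right tail).  The core's log-normal median
  is calibrated analytically so the *city-wide* sample median lands on
  the target (default 10).
* **Rural villages.**  The remainder are grouped into tight, spatially
  isolated clusters in the outer belt — villages of a few dozen postal
  codes with only a handful of residents each, the way an amalgamated
  city spans both downtown and countryside.  Isolation is not cosmetic:
  with spatially independent (or smoothly varying) populations, every
  k-nearest destination window can be covered by mass committed from a
  richer neighboring direction, and the worst-case risk constraints stay
  satisfiable no matter how small individual areas are.  Only a cluster
  larger than the neighbor-set size k, whose surroundings are equally
  population-poor (mean well below s/k), starves the worst-case model —
  while the small-area-aware model remains feasible there.

Everything is deterministic per seed; emitted tables satisfy every
LocationTable invariant and feed the rest of the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .geodata import LocationTable
from .randomize import PatientList

#: Rough extent of a mid-size amalgamated city (mimics Ottawa's bounding box).
DEFAULT_BBOX = (45.0, 45.6, -76.1, -75.3)

__all__ = ["DEFAULT_BBOX", "CitySpec", "generate_city", "ottawa_like", "sample_patients"]


@dataclass(frozen=True)
class CitySpec:
    """Parameters of a synthetic city.

    bbox is (lat_min, lat_max, lon_min, lon_max).  ``median_population``
    targets the city-wide sample median; ``sigma`` is the core log-normal
    shape.  ``rural_fraction`` of areas are placed in isolated villages of
    roughly ``village_size`` areas with log-normal populations of median
    ``village_median`` (shape ``village_sigma``); cities too small to host
    a village are all-core.
    """

    n_areas: int
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    median_population: float = 10.0
    sigma: float = 1.3
    rural_fraction: float = 0.25
    village_size: int = 70
    village_median: float = 2.5
    village_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        lat0, lat1, lon0, lon1 = self.bbox
        if not (lat0 < lat1 and lon0 < lon1):
            raise ValueError("bbox is degenerate")
        if self.median_population < 1:
            raise ValueError("target median population must be >= 1")
        if not 0 <= self.rural_fraction < 1:
            raise ValueError("rural_fraction must be in [0, 1)")


def ottawa_like(n_areas: int = 1000, seed: int = 0) -> CitySpec:
    """The default preset: city-wide median population 10, heavy tail,
    dense core plus isolated rural villages."""
    return CitySpec(n_areas=n_areas, seed=seed)


def _core_log_median(spec: CitySpec, n_rural: int, n_core: int) -> float:
    """Log-normal location for core areas so the city-wide median hits target.

    Populations are 1 + ⌊LogNormal⌋, so a draw below the target median M
    corresponds to the continuous variable falling below M − 0.5.  With
    rural share r below M with probability q_r, the core must fall below
    with probability (1/2 − r·q_r)/(1 − r).
    """
    target = spec.median_population - 0.5
    if n_rural == 0:
        return float(np.log(max(target, 0.5)))
    r = n_rural / (n_rural + n_core)
    q_rural = norm.cdf(
        np.log(target / max(spec.village_median - 0.5, 0.5)) / spec.village_sigma
    )
    q_core = np.clip((0.5 - r * q_rural) / (1.0 - r), 0.01, 0.99)
    return float(np.log(max(target, 0.5)) - norm.ppf(q_core) * spec.sigma)


def generate_city(spec: CitySpec) -> LocationTable:
    """Generate a location table from a city spec, deterministic per seed.

    Core centroids are uniform in the central half of the bbox; each
    village is a tight Gaussian cluster (σ ≈ 2% of the half-extent) on an
    outer ring, far enough from the core and from other villages that a
    village member's nearest areas are other village members.
    """
    rng = np.random.default_rng(spec.seed)
    lat0, lat1, lon0, lon1 = spec.bbox
    clat, clon = (lat0 + lat1) / 2, (lon0 + lon1) / 2
    hlat, hlon = (lat1 - lat0) / 2, (lon1 - lon0) / 2

    n_rural = int(round(spec.rural_fraction * spec.n_areas))
    n_villages = int(round(n_rural / spec.village_size)) if n_rural >= 10 else 0
    n_villages = max(n_villages, 1) if n_rural >= 10 else 0
    n_rural = 0 if n_villages == 0 else n_rural
    n_core = spec.n_areas - n_rural

    # Core: uniform within the inner half-extent.
    lat = [clat + rng.uniform(-0.5, 0.5, n_core) * hlat]
    lon = [clon + rng.uniform(-0.5, 0.5, n_core) * hlon]

    # Villages: centers evenly spaced in angle (jittered) on an outer ring.
    if n_villages:
        sizes = np.full(n_villages, n_rural // n_villages)
        sizes[: n_rural % n_villages] += 1
    else:
        sizes = np.empty(0, dtype=int)
    angles = (
        2 * np.pi * (np.arange(n_villages) + rng.uniform(0.2, 0.8, n_villages))
        / max(n_villages, 1)
    )
    for ang, size in zip(angles, sizes):
        radius = rng.uniform(0.78, 0.88)
        vlat = clat + radius * np.sin(ang) * hlat
        vlon = clon + radius * np.cos(ang) * hlon
        lat.append(np.clip(vlat + rng.normal(0, 0.02 * hlat, size), lat0, lat1))
        lon.append(np.clip(vlon + rng.normal(0, 0.02 * hlon, size), lon0, lon1))
    lat = np.concatenate(lat)
    lon = np.concatenate(lon)

    mu_core = _core_log_median(spec, n_rural, n_core)
    pop_core = 1 + np.floor(rng.lognormal(mu_core, spec.sigma, n_core))
    mu_rural = np.log(max(spec.village_median - 0.5, 0.5))
    pop_rural = 1 + np.floor(rng.lognormal(mu_rural, spec.village_sigma, n_rural))
    pop = np.concatenate([pop_core, pop_rural]).astype(np.int64)

    ids = tuple(f"A{i:05d}" for i in range(spec.n_areas))
    return LocationTable(area_ids=ids, lat=lat, lon=lon, population=pop)


def sample_patients(locations: LocationTable, s: int, seed: int) -> PatientList:
    """Draw s patients with origins proportional to population.

    Sampling is of individuals without replacement (multivariate
    hypergeometric over area populations), so no origin can receive more
    patients than it has residents, and s = N makes everyone a patient.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    N = locations.N
    if s > N:
        raise ValueError(f"s={s} exceeds the total population N={N}")
    rng = np.random.default_rng(seed)
    counts = rng.multivariate_hypergeometric(locations.population, s)
    pids = []
    areas = []
    p = 0
    for aid, cnt in zip(locations.area_ids, counts):
        for _ in range(int(cnt)):
            pids.append(f"P{p:06d}")
            areas.append(aid)
            p += 1
    return PatientList(tuple(pids), tuple(areas))
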