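"""Area tables, great-circle distances and nearest-k neighbor maps.

The spatial universe is a set of small areal units (postal/ZIP codes),
each represented by its centroid and resident population.  Distances are
great-circle ("as the crow flies") on a sphere; ellipsoidal effects are
ignored.  To keep downstream linear programs tractable, each origin's
admissible destinations are restricted to its k nearest areas (the origin
itself always included, at distance zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "LocationTable",
    "NeighborMap",
    "ValidationError",
    "haversine_m",
    "load_locations",
    "nearest_neighbors",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class LocationTable:
    """Validated table of areas: id, centroid (decimal degrees WGS84), population.

    ``N`` is the total population across all areas.  Populations must be
    at least 1 (areas with nobody in them carry no re-identification risk
    and no patients, and are excluded upstream).
    """

    area_ids: tuple[str, ...]
    lat: np.ndarray
    lon: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        ids = self.area_ids
        if len(ids) == 0:
            raise ValidationError("location table is empty")
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if list(ids).count(a) > 1})
            raise ValidationError(f"duplicate area_id values: {dupes[:5]}")
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        pop = np.asarray(self.population)
        if not (len(lat) == len(lon) == len(pop) == len(ids)):
            raise ValidationError("column lengths differ")
        if np.any(~np.isfinite(lat)) or np.any(lat < -90) or np.any(lat > 90):
            raise ValidationError("latitude out of range [-90, 90]")
        if np.any(~np.isfinite(lon)) or np.any(lon <= -180) or np.any(lon > 180):
            raise ValidationError("longitude out of range (-180, 180]")
        if np.any(pop != np.floor(pop)) or np.any(pop < 1):
            raise ValidationError("population must be an integer >= 1 for every area")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "population", pop.astype(np.int64))

    def __len__(self) -> int:
        return len(self.area_ids)

    @property
    def N(self) -> int:
        """Total population summed over all areas."""
        return int(self.population.sum())

    def index_of(self, area_id: str) -> int:
        try:
            return self._index[area_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {a: i for i, a in enumerate(self.area_ids)}
            )
            return self._index[area_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": self.area_ids,
                "lat": self.lat,
                "lon": self.lon,
                "population": self.population,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_locations(path, *, sep: str = ",") -> LocationTable:
    """Read a location CSV (header ``area_id,lat,lon,population``) and validate it."""
    df = pd.read_csv(path, sep=sep, dtype={"area_id": str})
    missing = {"area_id", "lat", "lon", "population"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    return LocationTable(
        area_ids=tuple(df["area_id"]),
        lat=df["lat"].to_numpy(float),
        lon=df["lon"].to_numpy(float),
        population=df["population"].to_numpy(),
    )


def haversine_m(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in meters between points given in decimal degrees.

    Spherical earth of mean radius 6,371,000 m.  Vectorized: any argument
    may be an array; broadcasting applies.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class NeighborMap:
    """Per-origin destination sets B_i, sorted by ascending distance.

    For each origin index i, ``dest_idx[i]`` holds destination indices into
    the location table and ``dist_m[i]`` the corresponding great-circle
    distances in meters.  Self is always present at distance 0 and sorts
    first; distance ties break on area_id lexicographic order so builds are
    deterministic.
    """

    area_ids: tuple[str, ...]
    dest_idx: tuple[np.ndarray, ...]
    dist_m: tuple[np.ndarray, ...]
    k: int = field(default=0)

    def __len__(self) -> int:
        return len(self.area_ids)

    @property
    def n_pairs(self) -> int:
        """Total number of (origin, destination) pairs, Σ_i |B_i|."""
        return int(sum(len(d) for d in self.dest_idx))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, aid in enumerate(self.area_ids):
            for j, d in zip(self.dest_idx[i], self.dist_m[i]):
                rows.append((aid, self.area_ids[int(j)], float(d)))
        return pd.DataFrame(rows, columns=["origin_id", "dest_id", "distance_m"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def nearest_neighbors(locations: LocationTable, k: int) -> NeighborMap:
    """Build the nearest-k neighbor map (self included, counting toward k).

    Each B_i holds the origin itself (d_ii = 0 makes it trivially nearest)
    plus the k−1 nearest other areas.  k larger than the number of areas is
    clamped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(locations)
    if k > n:
        warnings.warn(f"k={k} exceeds the number of areas ({n}); clamping", stacklevel=2)
        k = n
    # Full pairwise distance matrix; fine for the few-thousand-area scale
    # this library targets.
    lat = locations.lat
    lon = locations.lon
    dmat = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    dmat = np.atleast_2d(dmat)
    np.fill_diagonal(dmat, 0.0)

    ids = np.array(locations.area_ids)
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    dest_idx = []
    dist_m = []
    for i in range(n):
        # Self is a member of B_i by definition; the remaining k-1 slots go
        # to the nearest other areas, ties broken by area_id rank.
        others = np.lexsort((id_rank, dmat[i]))
        others = others[others != i][: k - 1]
        sel = np.concatenate(([i], others)).astype(np.int64)
        # Final ordering of the selection: ascending distance, then id.
        sel = sel[np.lexsort((id_rank[sel], dmat[i, sel]))]
        dest_idx.append(sel)
        dist_m.append(dmat[i, sel])
    return NeighborMap(
        area_ids=locations.area_ids,
        dest_idx=tuple(dest_idx),
        dist_m=tuple(dist_m),
        k=k,
    )
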