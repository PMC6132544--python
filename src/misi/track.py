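"""Tracking-data model and I/O.

Tracks are tabular: one row per Argos/GPS fix with an individual id, a trip
id, a UTC timestamp and a geographic position.  Fixes are grouped into
:class:`Trip` objects (one central-place foraging trip) and collected in a
:class:`Dataset`.  Positions are projected to a planar, equal-area coordinate
system (South-Pole Lambert azimuthal equal-area) before any distance or
hull computation, so that areas and volumes are meaningful in metres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS",
    "Behaviour",
    "SouthPolarLAEA",
    "Trip",
    "Dataset",
    "SchemaError",
    "DataError",
    "read_tracks",
    "write_tracks",
    "project",
    "haversine_m",
]

#: Authalic Earth radius in metres (sphere with the same surface area as the
#: WGS84 ellipsoid) — the natural choice for an equal-area projection.
EARTH_RADIUS = 6_371_007.1809


class Behaviour:
    """Behavioural labels attached to fixes."""

    UNCLASSIFIED = "unclassified"
    TRANSIT = "transit"
    FORAGING = "foraging"
    RESTING = "resting"

    ALL = (UNCLASSIFIED, TRANSIT, FORAGING, RESTING)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class DataError(ValueError):
    """Rows violate the data contract (e.g. duplicate timestamps)."""


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SouthPolarLAEA:
    """Lambert azimuthal equal-area projection, South-Pole aspect.

    Spherical formulation (Snyder 1987, eqs. 24-2/24-13 with ``lat_0 = -90``)
    on the authalic sphere.  Any ``lon_0`` preserves the equal-area property;
    0° is the conventional default.  Coordinates are in metres; the pole maps
    to the origin.
    """

    lon_0: float = 0.0
    radius: float = EARTH_RADIUS

    def forward(self, lon, lat):
        """Project geographic degrees to planar metres ``(x, y)``.

        The antipode of the projection centre (the North Pole) is singular
        and raises.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(lat > 90.0) or np.any(lat < -90.0):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(lat >= 90.0 - 1e-9):
            raise ValueError("North Pole is the antipode of this projection")
        phi = np.radians(lat)
        dlam = np.radians(lon - self.lon_0)
        # k' = sqrt(2 / (1 - sin(phi))) for the south-polar aspect
        kp = np.sqrt(2.0 / (1.0 - np.sin(phi)))
        x = self.radius * kp * np.cos(phi) * np.sin(dlam)
        y = self.radius * kp * np.cos(phi) * np.cos(dlam)
        return x, y

    def inverse(self, x, y):
        """Planar metres back to geographic degrees ``(lon, lat)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        with np.errstate(invalid="ignore"):
            c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), 0.0, 1.0))
        lat = np.degrees(np.arcsin(-np.cos(c)))
        lon = self.lon_0 + np.degrees(np.arctan2(x, y))
        # At the pole itself the longitude is undefined; pin it to lon_0.
        lon = np.where(rho == 0.0, self.lon_0, lon)
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, lat


def haversine_m(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS):
    """Great-circle distance in metres on the authalic sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(h))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

#: Canonical fix-table columns.  ``t`` is a tz-aware UTC timestamp; ``x``/``y``
#: are planar metres (NaN until projected).
FIX_COLUMNS = ["individual_id", "trip_id", "t", "lon", "lat", "x", "y", "behaviour"]


@dataclass
class Trip:
    """One foraging trip: an ordered sequence of fixes for one individual."""

    trip_id: object
    individual_id: object
    fixes: pd.DataFrame

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise DataError(f"trip {self.trip_id!r}: a trip needs at least 2 fixes")
        t = self.fixes["t"].to_numpy()
        if not (t[1:] > t[:-1]).all():
            raise DataError(f"trip {self.trip_id!r}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def duration_s(self) -> float:
        t = self.fixes["t"]
        return float((t.iloc[-1] - t.iloc[0]).total_seconds())

    def xy(self) -> np.ndarray:
        """Projected positions as an ``(n, 2)`` array of metres."""
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def seconds(self) -> np.ndarray:
        """Timestamps as seconds since the first fix."""
        t = self.fixes["t"]
        return (t - t.iloc[0]).dt.total_seconds().to_numpy()


@dataclass
class Dataset:
    """All trips of a tracked population, stored as one fix table."""

    fixes: pd.DataFrame
    n_rejected: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def individuals(self) -> list:
        return sorted(self.fixes["individual_id"].unique().tolist())

    @property
    def trip_ids(self) -> list:
        return sorted(self.fixes["trip_id"].unique().tolist())

    @property
    def n_trips(self) -> int:
        return self.fixes["trip_id"].nunique()

    def trip_counts(self) -> dict:
        """Number of trips per individual (the empirical multiset)."""
        g = self.fixes.drop_duplicates("trip_id").groupby("individual_id")["trip_id"].count()
        return g.to_dict()

    def trips(self) -> Iterator[Trip]:
        for trip_id, df in self.fixes.groupby("trip_id", sort=True):
            yield Trip(trip_id, df["individual_id"].iloc[0], df.reset_index(drop=True))

    def trip(self, trip_id) -> Trip:
        df = self.fixes[self.fixes["trip_id"] == trip_id]
        if df.empty:
            raise KeyError(trip_id)
        return Trip(trip_id, df["individual_id"].iloc[0], df.reset_index(drop=True))

    def map_trips(self, fn: Callable[[Trip], Trip]) -> "Dataset":
        """Apply a per-trip transform and reassemble the dataset."""
        parts = [fn(trip).fixes for trip in self.trips()]
        out = pd.concat(parts, ignore_index=True)
        return Dataset(out, n_rejected=self.n_rejected, metadata=dict(self.metadata))

    def validate(self) -> None:
        for trip in self.trips():
            pass  # Trip.__post_init__ enforces the per-trip invariants
        per_trip_ind = self.fixes.groupby("trip_id")["individual_id"].nunique()
        if (per_trip_ind > 1).any():
            bad = per_trip_ind[per_trip_ind > 1].index.tolist()
            raise DataError(f"trips assigned to multiple individuals: {bad}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "individual_id": "individual_id",
    "trip_id": "trip_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}


def read_tracks(
    path,
    schema: dict | None = None,
    prefilter: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> Dataset:
    """Read a tracking CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns (under ``schema``
        renaming): individual_id, trip_id, timestamp (ISO 8601, UTC), lon,
        lat.  An optional ``sex`` column is carried as per-individual
        metadata.
    schema
        Mapping from canonical names to the file's column names.
    prefilter
        Optional hook applied to the raw (renamed) table before grouping,
        e.g. a speed filter.  No filter is applied by default.

    Rows with unparseable timestamps or coordinates, and trips with fewer
    than two usable fixes, are dropped; the count is reported in
    ``Dataset.n_rejected``.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path)
    missing = [src for src in schema.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw.rename(columns={v: k for k, v in schema.items()})

    if prefilter is not None:
        df = prefilter(df)

    n0 = len(df)
    t = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        t.notna()
        & lon.notna()
        & lat.notna()
        & lon.between(-180, 180)
        & lat.between(-90, 90)
        & df["individual_id"].notna()
        & df["trip_id"].notna()
    )
    fixes = pd.DataFrame(
        {
            "individual_id": df.loc[ok, "individual_id"],
            "trip_id": df.loc[ok, "trip_id"],
            "t": t[ok],
            "lon": lon[ok],
            "lat": lat[ok],
            "x": np.nan,
            "y": np.nan,
            "behaviour": Behaviour.UNCLASSIFIED,
        }
    )
    if "behaviour" in df.columns:
        fixes["behaviour"] = df.loc[ok, "behaviour"].fillna(Behaviour.UNCLASSIFIED)

    dup = fixes.duplicated(subset=["trip_id", "t"], keep=False)
    if dup.any():
        raise DataError(
            f"{int(dup.sum())} duplicate (trip_id, timestamp) rows — fix the input file"
        )

    fixes = fixes.sort_values(["trip_id", "t"], kind="stable").reset_index(drop=True)
    # drop trips that cannot form a Trip (fewer than 2 usable fixes)
    sizes = fixes.groupby("trip_id")["t"].transform("size")
    fixes = fixes[sizes >= 2].reset_index(drop=True)
    n_rejected = n0 - len(fixes)

    meta = {}
    if "sex" in df.columns:
        meta["sex"] = (
            df.loc[ok].groupby("individual_id")["sex"].first().to_dict()
        )
    ds = Dataset(fixes, n_rejected=n_rejected, metadata=meta)
    ds.validate()
    if n_rejected:
        warnings.warn(f"read_tracks: rejected {n_rejected} row(s)", stacklevel=2)
    return ds


def write_tracks(dataset: Dataset, path) -> None:
    """Write the fix table back to CSV (input schema plus x, y, behaviour)."""
    out = dataset.fixes.copy()
    out["timestamp"] = out.pop("t").dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    cols = ["individual_id", "trip_id", "timestamp", "lon", "lat", "x", "y", "behaviour"]
    out[cols].to_csv(path, index=False)


def project(dataset: Dataset, projection: SouthPolarLAEA | None = None) -> Dataset:
    """Populate planar ``x``, ``y`` (metres) on every fix."""
    projection = projection or SouthPolarLAEA()
    fixes = dataset.fixes.copy()
    x, y = projection.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("projection produced non-finite coordinates")
    fixes["x"] = x
    fixes["y"] = y
    out = Dataset(fixes, n_rejected=dataset.n_rejected, metadata=dict(dataset.metadata))
    out.metadata["projection"] = {"name": "south_polar_laea", "lon_0": projection.lon_0}
    return out
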