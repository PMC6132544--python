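"""Environmental annotation and niche-space construction.

Foraging fixes are annotated with gridded oceanographic fields (sea-surface
temperature, eddy kinetic energy, depth) by nearest-date, containing-cell
lookup, then mapped into a d-dimensional *niche space*: EKE is
log-transformed (to tame its heavy right skew) and every variable is
z-scored against the pooled mean/SD of all individuals so each dimension
carries equal weight.  In geographic mode the niche space is simply the
projected (x, y) plane — same units, so no standardisation.

A tiny uniform jitter (±5e-5 on the standardised scale) is applied before
hull construction to break the exact coordinate ties that make polytopes
degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "RasterField",
    "StandardisationSpec",
    "extract_env",
    "annotate",
    "build_niche_space",
    "jitter",
    "niche_frame",
    "JITTER_HALF_WIDTH",
]

#: Default half-width of the degeneracy-breaking uniform jitter
#: (on the standardised scale).
JITTER_HALF_WIDTH = 5e-5


@dataclass
class RasterField:
    """A (possibly dated) stack of regular lon/lat grids for one variable.

    ``values`` has shape (n_layers, n_lat, n_lon); ``lon``/``lat`` are cell
    *centre* coordinates, evenly spaced and ascending.  ``dates`` is None for
    a static field (e.g. bathymetry), else one datetime64 per layer,
    ascending.
    """

    name: str
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    dates: np.ndarray | None = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        if self.values.shape[1:] != (self.lat.size, self.lon.size):
            raise ValueError(f"{self.name}: grid shape does not match coordinates")
        if self.dates is not None:
            self.dates = np.asarray(self.dates, dtype="datetime64[ns]")
            if self.dates.size != self.values.shape[0]:
                raise ValueError(f"{self.name}: one date per layer required")
            if not (np.diff(self.dates) > np.timedelta64(0, "ns")).all():
                raise ValueError(f"{self.name}: layer dates must be ascending")

    @property
    def resolution(self) -> float:
        return float(np.diff(self.lon).mean())

    def to_dataarray(self) -> xr.DataArray:
        coords = {"lat": self.lat, "lon": self.lon}
        dims = ("lat", "lon")
        if self.dates is not None:
            coords = {"time": self.dates, **coords}
            dims = ("time",) + dims
            data = self.values
        else:
            data = self.values[0]
        return xr.DataArray(data, coords=coords, dims=dims, name=self.name)

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "RasterField":
        dates = da["time"].to_numpy() if "time" in da.dims else None
        vals = da.transpose(*(("time",) if dates is not None else ()), "lat", "lon").to_numpy()
        return cls(da.name or "field", da["lon"].to_numpy(), da["lat"].to_numpy(), vals, dates)

    # -- plain-text persistence (long format: date,lat,lon,value) ----------

    def to_csv(self, path) -> None:
        da = self.to_dataarray()
        df = da.to_dataframe(name="value").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str) -> "RasterField":
        df = pd.read_csv(path)
        lon = np.sort(df["lon"].unique())
        lat = np.sort(df["lat"].unique())
        if "time" in df.columns:
            df["time"] = pd.to_datetime(df["time"])
            dates = np.sort(df["time"].unique())
            piv = (
                df.set_index(["time", "lat", "lon"])["value"]
                .unstack(["lat", "lon"])
                .sort_index()
            )
            vals = piv.to_numpy().reshape(dates.size, lat.size, lon.size)
        else:
            dates = None
            vals = df.pivot(index="lat", columns="lon", values="value").sort_index().to_numpy()
        return cls(name, lon, lat, vals, dates)

    def _layer_for(self, when) -> np.ndarray:
        """Index of the layer with the nearest date (earlier layer on a tie)."""
        if self.dates is None:
            return np.zeros(len(when), dtype=int)
        when = pd.DatetimeIndex(when)
        if when.tz is not None:
            when = when.tz_convert(None)
        diffs = np.abs(when.to_numpy()[:, None] - self.dates[None, :])
        return np.argmin(diffs, axis=1)  # argmin → first (earlier) on ties


def extract_env(fixes: pd.DataFrame, fld: RasterField) -> tuple[np.ndarray, np.ndarray]:
    """Value of the raster cell containing each fix, from the layer nearest
    in date.  Returns ``(values, missing_mask)``; fixes outside the raster
    extent or hitting a NaN cell are flagged missing (value NaN).
    """
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)

    def cell_index(coord, centers):
        step = np.diff(centers).mean()
        edges = np.concatenate([[centers[0] - step / 2], centers + step / 2])
        idx = np.searchsorted(edges, coord, side="right") - 1
        ok = (idx >= 0) & (idx < centers.size)
        return np.clip(idx, 0, centers.size - 1), ok

    i_lon, ok_lon = cell_index(lon, fld.lon)
    i_lat, ok_lat = cell_index(lat, fld.lat)
    layer = fld._layer_for(fixes["t"]) if fld.dates is not None else np.zeros(
        len(fixes), dtype=int
    )
    vals = fld.values[layer, i_lat, i_lon]
    missing = ~(ok_lon & ok_lat) | ~np.isfinite(vals)
    vals = np.where(missing, np.nan, vals)
    return vals, missing


def annotate(fixes: pd.DataFrame, fields: list[RasterField]) -> pd.DataFrame:
    """Add one column per environmental field; keeps the missing flags in
    ``<name>_missing`` columns."""
    out = fixes.copy()
    for fld in fields:
        vals, missing = extract_env(fixes, fld)
        out[fld.name] = vals
        out[f"{fld.name}_missing"] = missing
    return out


# ---------------------------------------------------------------------------
# Standardisation and niche coordinates
# ---------------------------------------------------------------------------


@dataclass
class StandardisationSpec:
    """Per-variable transform + pooled moments, so the mapping into niche
    space is reusable (e.g. on the permutation sets) and invertible."""

    variables: list
    transforms: dict = field(default_factory=dict)  # name -> "identity" | "log"
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def apply_one(self, name: str, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.transforms.get(name, "identity") == "log":
            v = np.log(v)
        return (v - self.means[name]) / self.sds[name]

    def invert_one(self, name: str, coords: np.ndarray) -> np.ndarray:
        v = np.asarray(coords, dtype=float) * self.sds[name] + self.means[name]
        if self.transforms.get(name, "identity") == "log":
            v = np.exp(v)
        return v


def build_niche_space(
    fixes: pd.DataFrame,
    variables: list[str] | None = None,
    mode: str = "environmental",
    log_vars: tuple = ("eke",),
    log_base: str = "natural",
) -> tuple[pd.DataFrame, StandardisationSpec]:
    """Map annotated foraging fixes into niche coordinates.

    Environmental mode: per variable, apply the transform (natural log for
    EKE by default — the choice of base is immaterial after z-scoring, but a
    ``log_base='10'`` switch is provided), then z-score against the pooled
    mean/SD over all retained fixes of all individuals.  Fixes with any
    missing value (including non-positive EKE, where the log is undefined)
    are dropped and the dropped fraction reported.

    Geographic mode: coordinates are the projected (x, y) metres,
    unstandardised.

    Returns a *niche frame* — a DataFrame with ``individual_id``,
    ``trip_id`` and coordinate columns ``c0..c{d-1}`` — plus the spec.
    """
    if mode == "geographic":
        pts = niche_frame(fixes, fixes[["x", "y"]].to_numpy(dtype=float))
        spec = StandardisationSpec(
            variables=["x", "y"],
            transforms={},
            means={"x": 0.0, "y": 0.0},
            sds={"x": 1.0, "y": 1.0},
        )
        return pts, spec
    if mode != "environmental":
        raise ValueError("mode must be 'geographic' or 'environmental'")
    if variables is None:
        variables = [
            c for c in ("sst", "eke", "depth") if c in fixes.columns
        ]
    if not variables:
        raise ValueError("no environmental variables found — annotate first")

    work = fixes.copy()
    ok = np.ones(len(work), dtype=bool)
    for name in variables:
        v = work[name].to_numpy(dtype=float)
        bad = ~np.isfinite(v)
        if name in log_vars:
            bad |= v <= 0.0  # log undefined; physical EKE is positive
        ok &= ~bad
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped}/{len(work)} fixes with missing environmental values",
            stacklevel=2,
        )
    work = work[ok].reset_index(drop=True)

    transforms = {name: ("log" if name in log_vars else "identity") for name in variables}
    means, sds = {}, {}
    cols = []
    for name in variables:
        v = work[name].to_numpy(dtype=float)
        if transforms[name] == "log":
            v = np.log(v) if log_base == "natural" else np.log10(v)
        # sample SD (n-1 denominator), the convention of the R ecosystem the
        # method grew up in
        m, sd = float(v.mean()), float(v.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"variable {name!r} is constant — degenerate niche dimension")
        means[name], sds[name] = m, sd
        cols.append((v - m) / sd)
    spec = StandardisationSpec(list(variables), transforms, means, sds)
    pts = niche_frame(work, np.column_stack(cols))
    pts.attrs["n_dropped"] = n_dropped
    return pts, spec


def niche_frame(fixes: pd.DataFrame, coords: np.ndarray) -> pd.DataFrame:
    """Assemble the canonical analysis table: individual/trip identifiers
    plus coordinate columns c0..c{d-1}."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.isfinite(coords).all():
        raise ValueError("niche coordinates must be finite")
    out = pd.DataFrame(
        {
            "individual_id": fixes["individual_id"].to_numpy(),
            "trip_id": fixes["trip_id"].to_numpy(),
        }
    )
    for j in range(coords.shape[1]):
        out[f"c{j}"] = coords[:, j]
    return out


def coord_columns(points: pd.DataFrame) -> list[str]:
    return [c for c in points.columns if c.startswith("c") and c[1:].isdigit()]


def jitter(
    points: pd.DataFrame,
    half_width: float = JITTER_HALF_WIDTH,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Perturb every coordinate by an independent Uniform(−half_width,
    +half_width) draw.  Applied after standardisation, where the default
    magnitude is negligible relative to unit variance but sufficient to
    break exact ties that would make local hulls flat."""
    rng = rng if rng is not None else np.random.default_rng()
    out = points.copy()
    cols = coord_columns(points)
    if half_width > 0:
        noise = rng.uniform(-half_width, half_width, size=(len(points), len(cols)))
        out[cols] = points[cols].to_numpy() + noise
    return out
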