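"""The Multidimensional Individual Specialisation Index.

For individual *i* with niche hypervolume WIC_i (within-individual
component) and population total niche volume TNV (the union hypervolume of
all individuals on the same grid),

    MISI_i = 1 - WIC_i / TNV ,

so MISI_i = 0 means the individual uses the population's whole niche
(generalist) and values approaching 1 mean it uses a vanishing fraction of
it (specialist).  The population-level summary is the median over
individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import coord_columns
from .locoh import GridSpec, Hypervolume, LocohParams, individual_hypervolume, union_volume

__all__ = ["MISIResult", "compute_misi", "individual_hypervolumes", "misi_from_points"]


@dataclass
class MISIResult:
    """Per-individual WIC/MISI plus the population TNV and median MISI."""

    per_individual: pd.DataFrame  # individual_id, n_points, n_ignored, wic, misi
    tnv: float
    median_misi: float
    grid: GridSpec
    tnv_cells: frozenset

    @property
    def wic(self) -> dict:
        return dict(zip(self.per_individual["individual_id"], self.per_individual["wic"]))

    @property
    def misi(self) -> dict:
        return dict(zip(self.per_individual["individual_id"], self.per_individual["misi"]))


def compute_misi(hypervolumes: dict[object, Hypervolume]) -> MISIResult:
    """MISI from per-individual hypervolumes on one shared grid.

    TNV is the union volume over all individuals; individuals with an empty
    hypervolume (every point ignored) get an undefined (NaN) MISI, excluded
    from the median, with a warning.
    """
    if not hypervolumes:
        raise ValueError("need at least one individual")
    union = union_volume(list(hypervolumes.values()))
    tnv = union.volume
    if tnv == 0.0:
        raise ValueError("TNV is zero — the index is undefined")
    rows = []
    for ind in sorted(hypervolumes, key=str):
        hv = hypervolumes[ind]
        wic = hv.volume
        misi = 1.0 - wic / tnv if wic > 0 else np.nan
        if wic == 0:
            warnings.warn(f"individual {ind!r} has an empty hypervolume; MISI undefined",
                          stacklevel=2)
        rows.append(
            {
                "individual_id": ind,
                "n_points": hv.n_points_used + hv.n_points_ignored,
                "n_ignored": hv.n_points_ignored,
                "wic": wic,
                "misi": misi,
            }
        )
    per = pd.DataFrame(rows)
    return MISIResult(
        per_individual=per,
        tnv=tnv,
        median_misi=float(np.nanmedian(per["misi"].to_numpy())),
        grid=union.grid,
        tnv_cells=union.cells,
    )


def individual_hypervolumes(
    points: pd.DataFrame,
    params: LocohParams,
    grid: GridSpec,
    strict: bool = False,
) -> dict[object, Hypervolume]:
    """One a-LoCoH hypervolume per individual from a niche frame
    (columns ``individual_id``, ``trip_id``, ``c0..``)."""
    cols = coord_columns(points)
    if len(cols) != params.d:
        raise ValueError(f"niche frame has {len(cols)} dimensions, params.d = {params.d}")
    out = {}
    for ind, df in points.groupby("individual_id", sort=True):
        out[ind] = individual_hypervolume(
            df[cols].to_numpy(dtype=float), params, grid, strict=strict
        )
    return out


def misi_from_points(
    points: pd.DataFrame,
    params: LocohParams,
    grid: GridSpec | None = None,
    grid_margin: int = 1,
    strict: bool = False,
) -> MISIResult:
    """End-to-end index from a niche frame; builds the shared grid from the
    pooled cloud when none is given."""
    cols = coord_columns(points)
    if grid is None:
        grid = GridSpec.from_points(points[cols].to_numpy(dtype=float), _grain_for(params), grid_margin)
    hvs = individual_hypervolumes(points, params, grid, strict=strict)
    return compute_misi(hvs)


def _grain_for(params: LocohParams) -> float:
    # a sensible default when the caller gives no grid: 1/16 of a
    return params.a / 16.0
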