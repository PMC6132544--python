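"""Parameter-choice diagnostics, end-to-end pipeline and reporting.

Two knobs govern the hypervolumes and both are chosen empirically, not
automatically:

* the a-LoCoH parameter ``a`` — too small and points fall out of the
  hypervolume (holes, ignored outliers); too large and the hypervolume
  swallows space the animal never used.  :func:`diagnose_a` tabulates the
  ignored-point fraction and total volume over a candidate range and can
  plot occupied cells over the points (2-D projections) for visual
  assessment.
* the grid grain — refined until the MISI values stabilise;
  :func:`diagnose_grain` tabulates volume and MISI against grain and flags
  the coarsest grain whose successive change is below 1%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import env as env_mod
from . import preprocess as pre_mod
from .env import RasterField, build_niche_space, coord_columns, jitter
from .locoh import (
    DEFAULT_A_ENVIRONMENTAL,
    DEFAULT_A_GEOGRAPHIC,
    DEFAULT_GRAIN_ENVIRONMENTAL,
    DEFAULT_GRAIN_GEOGRAPHIC,
    GridSpec,
    LocohParams,
    Polytope,
    local_polytopes,
    occupancy,
)
from .nullmodel import NullConfig, NullDistribution, null_test
from .specialisation import MISIResult
from .track import Dataset, SouthPolarLAEA, project, read_tracks

__all__ = [
    "RunConfig",
    "diagnose_a",
    "diagnose_grain",
    "run_pipeline",
    "null_histogram",
]


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def diagnose_a(
    cloud: np.ndarray,
    a_values,
    grain: float,
    figures_dir=None,
    strict: bool = False,
) -> pd.DataFrame:
    """Ignored-point fraction and total volume for each candidate ``a``.

    No automatic choice is made — the table (and the optional cell-over-point
    overlay figures) supports the user's visual decision.
    """
    cloud = np.asarray(cloud, dtype=float)
    a_values = sorted(a_values)
    if len(a_values) < 2:
        raise ValueError("give at least 2 candidate a values")
    d = cloud.shape[1]
    rows = []
    for a in a_values:
        params = LocohParams(a=float(a), d=d)
        polys, n_ignored, _ = local_polytopes(cloud, params, strict=strict)
        verts = np.vstack([p.vertices for p in polys]) if polys else cloud
        grid = GridSpec.from_points(np.vstack([cloud, verts]), grain)
        hv = occupancy(polys, grid)
        rows.append(
            {
                "a": float(a),
                "n_ignored": n_ignored,
                "frac_ignored": n_ignored / len(cloud),
                "n_cells": len(hv),
                "volume": hv.volume,
            }
        )
        if figures_dir is not None:
            _plot_occupancy_2d(cloud, hv, Path(figures_dir) / f"a_{a:g}")
    return pd.DataFrame(rows)


def _plot_occupancy_2d(cloud: np.ndarray, hv, stem: Path) -> None:
    stem.parent.mkdir(parents=True, exist_ok=True)
    d = cloud.shape[1]
    cents = hv.grid.centroids(hv.cells) if hv.cells else np.empty((0, d))
    for i, j in [(i, j) for i in range(d) for j in range(i + 1, d)]:
        fig, ax = plt.subplots(figsize=(5, 5))
        if len(cents):
            ax.scatter(cents[:, i], cents[:, j], s=6, c="#9ecae1", marker="s",
                       label="occupied cells")
        ax.scatter(cloud[:, i], cloud[:, j], s=4, c="k", label="points")
        ax.set_xlabel(f"dim {i}")
        ax.set_ylabel(f"dim {j}")
        ax.legend(loc="best", fontsize=8)
        fig.savefig(f"{stem}_d{i}{j}.png", dpi=120)
        plt.close(fig)


def diagnose_grain(
    polytopes_by_individual: dict[object, list[Polytope]],
    grains,
    rel_tol: float = 0.01,
) -> tuple[pd.DataFrame, float | None]:
    """Volume and MISI per individual across decreasing grains.

    Returns the long table (grain, individual, volume, misi, plus per-grain
    tnv and median_misi) and the coarsest grain at which the successive
    change in median MISI drops below ``rel_tol``, or None if it never
    stabilises within the sequence.
    """
    grains = list(grains)
    if any(g <= 0 for g in grains) or any(b >= a for a, b in zip(grains, grains[1:])):
        raise ValueError("grains must be positive and strictly decreasing")
    all_verts = np.vstack(
        [p.vertices for polys in polytopes_by_individual.values() for p in polys]
    )
    rows = []
    medians = []
    for grain in grains:
        grid = GridSpec.from_points(all_verts, float(grain))
        hvs = {
            ind: occupancy(polys, grid) for ind, polys in polytopes_by_individual.items()
        }
        cells = frozenset().union(*(hv.cells for hv in hvs.values()))
        tnv = len(cells) * grid.grain ** grid.d
        misis = {ind: 1.0 - hv.volume / tnv for ind, hv in hvs.items()}
        medians.append(float(np.median(list(misis.values()))))
        for ind, hv in hvs.items():
            rows.append(
                {
                    "grain": float(grain),
                    "individual_id": ind,
                    "volume": hv.volume,
                    "misi": misis[ind],
                    "tnv": tnv,
                    "median_misi": medians[-1],
                }
            )
    stable = None
    for k in range(1, len(grains)):
        denom = max(abs(medians[k - 1]), 1e-12)
        if abs(medians[k] - medians[k - 1]) / denom < rel_tol:
            stable = float(grains[k - 1])
            break
    return pd.DataFrame(rows), stable


def null_histogram(dist: NullDistribution, path) -> None:
    """Null-median histogram with dashed 95% CI lines and a solid line at
    the empirical median."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(dist.medians, bins=20, color="#bdbdbd", edgecolor="white")
    for v in (dist.ci_low, dist.ci_high):
        ax.axvline(v, color="tab:blue", linestyle="--", label="95% CI")
    ax.axvline(dist.empirical_median, color="tab:red", linestyle="-", label="empirical")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=8)
    ax.set_xlabel("median MISI")
    ax.set_ylabel("null sets")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full-pipeline configuration (flat; YAML-serialisable; every field has
    a CLI twin and the CLI wins on conflict)."""

    tracks: str = ""
    space: str = "geographic"  # or "environmental"
    a: float | None = None  # default depends on space
    grain: float | None = None
    radius_m: float = 45_000.0
    threshold_s: float = 25_000.0
    daylight: bool = True
    immersion: str | None = None
    rasters: dict = field(default_factory=dict)  # name -> csv path
    n_sets: int = 100
    seed: int | None = None
    jitter_half_width: float = env_mod.JITTER_HALF_WIDTH
    strict_neighbours: bool = False
    out_dir: str = "misi_out"
    figures: bool = True

    def __post_init__(self):
        if self.space not in ("geographic", "environmental"):
            raise ValueError("space must be 'geographic' or 'environmental'")
        if self.a is None:
            self.a = (
                DEFAULT_A_GEOGRAPHIC if self.space == "geographic" else DEFAULT_A_ENVIRONMENTAL
            )
        if self.grain is None:
            self.grain = (
                DEFAULT_GRAIN_GEOGRAPHIC
                if self.space == "geographic"
                else DEFAULT_GRAIN_ENVIRONMENTAL
            )
        for name, val in (("a", self.a), ("grain", self.grain),
                          ("radius_m", self.radius_m), ("threshold_s", self.threshold_s)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Read → preprocess → (annotate) → hypervolumes → MISI → null test.

    Writes the per-individual table, the null-median list, a structured
    summary (JSON) and a structured log of every parameter and seed to
    ``config.out_dir``, plus the null-histogram figure.  Returns the bundle
    in memory: ``{"misi": MISIResult, "null": NullDistribution, ...}``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if dataset is None:
            dataset = read_tracks(config.tracks)
        if dataset.fixes[["x", "y"]].isna().any().any():
            dataset = project(dataset, SouthPolarLAEA())
    except Exception as e:  # noqa: BLE001 - stage-labelled re-raise
        raise RuntimeError(f"[read] {e}") from e

    try:
        immersion = (
            pre_mod.read_immersion(config.immersion) if config.immersion else None
        )
        foraging = pre_mod.select_foraging(
            dataset,
            radius_m=config.radius_m,
            threshold_s=config.threshold_s,
            daylight=config.daylight,
            immersion=immersion,
        )
        if foraging.fixes.empty:
            raise ValueError("no foraging fixes survive filtering")
    except Exception as e:
        raise RuntimeError(f"[preprocess] {e}") from e

    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    try:
        if config.space == "environmental":
            if not config.rasters:
                raise ValueError("environmental mode needs raster inputs (sst/eke/depth)")
            fields = [RasterField.from_csv(p, name) for name, p in config.rasters.items()]
            annotated = env_mod.annotate(foraging.fixes, fields)
            points, std_spec = build_niche_space(annotated, mode="environmental")
            points = jitter(points, config.jitter_half_width, rng)
        else:
            points, std_spec = build_niche_space(foraging.fixes, mode="geographic")
    except Exception as e:
        raise RuntimeError(f"[niche-space] {e}") from e

    try:
        d = len(coord_columns(points))
        params = LocohParams(a=float(config.a), d=d)
        grid = GridSpec.from_points(
            points[coord_columns(points)].to_numpy(dtype=float), float(config.grain)
        )
        result, dist = null_test(
            points,
            params,
            NullConfig(n_sets=config.n_sets, seed=config.seed),
            grid=grid,
            strict=config.strict_neighbours,
        )
    except Exception as e:
        raise RuntimeError(f"[misi] {e}") from e

    # --- outputs ---------------------------------------------------------
    result.per_individual.to_csv(out / "misi_per_individual.csv", index=False)
    pd.DataFrame({"null_median_misi": dist.medians}).to_csv(
        out / "null_medians.csv", index=False
    )
    cents = result.grid.centroids(sorted(result.tnv_cells))
    cells_df = pd.DataFrame(cents, columns=[f"c{i}" for i in range(cents.shape[1])])
    cells_df.insert(0, "cell", sorted(result.tnv_cells))
    cells_df.to_csv(out / "tnv_cells.csv", index=False)

    summary = {
        "space": config.space,
        "n_individuals": int(result.per_individual.shape[0]),
        "n_points": int(len(points)),
        "tnv": result.tnv,
        "median_misi": result.median_misi,
        "ci_low": dist.ci_low,
        "ci_high": dist.ci_high,
        "p_value": dist.p_value,
        "p_value_add_one": dist.p_value_add_one,
        "specialised": bool(dist.p_value < 0.05),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    log = {
        "config": config.to_dict(),
        "n_interpolated": foraging.metadata.get("n_interpolated"),
        "n_foraging": foraging.metadata.get("n_foraging"),
        "grid": {"origin": list(grid.origin), "grain": grid.grain, "shape": list(grid.shape)},
        "params": {"a": params.a, "d": params.d},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))

    if config.figures:
        null_histogram(dist, out / "null_histogram.png")

    return {
        "misi": result,
        "null": dist,
        "points": points,
        "summary": summary,
        "foraging": foraging,
        "standardisation": std_spec,
    }
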