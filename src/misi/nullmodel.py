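"""Trip-identity permutation null model for the specialisation test.

Are individuals more specialised than expected by chance?  "Null
individuals" are assembled by dealing the real trips out at random, whole
and without replacement, keeping the empirical per-individual trip-count
multiset.  Keeping trips intact preserves the within-trip spatial and
temporal autocorrelation; shuffling identity destroys any between-trip
consistency of real individuals.  For each of ``n_sets`` shuffles the
per-individual hypervolumes and the median MISI are recomputed (TNV held at
the empirical population value — the pooled point cloud, and hence the
population niche, is unchanged by reassigning trip labels).  The one-sided
p-value is the proportion of null medians strictly greater than the
empirical median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import coord_columns
from .locoh import GridSpec, LocohParams, individual_hypervolume
from .specialisation import MISIResult, misi_from_points
from .track import Dataset

__all__ = [
    "NullConfig",
    "NullDistribution",
    "shuffle_trips",
    "shuffle_assignment",
    "null_test",
    "summarise_null",
]


@dataclass(frozen=True)
class NullConfig:
    """Null-model settings: number of permutation sets (default 100) and the
    master seed.  Each set draws from an independently spawned child
    generator, so sets are reproducible and independent regardless of
    execution order."""

    n_sets: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass
class NullDistribution:
    """Permutation distribution of the population median MISI."""

    medians: np.ndarray
    empirical_median: float
    ci_low: float
    ci_high: float
    p_value: float
    p_value_add_one: float  # (b + 1) / (n + 1) estimator, never exactly zero

    def __post_init__(self):
        self.medians = np.asarray(self.medians, dtype=float)


def shuffle_assignment(
    trip_to_individual: dict, rng: np.random.Generator
) -> dict:
    """Uniform random reassignment of whole trips to individuals, conserving
    the per-individual trip-count multiset (a permutation of trip labels:
    every trip is used exactly once, none duplicated)."""
    trips = sorted(trip_to_individual, key=str)
    individuals = sorted({trip_to_individual[t] for t in trips}, key=str)
    counts = {ind: 0 for ind in individuals}
    for t in trips:
        counts[trip_to_individual[t]] += 1
    perm = rng.permutation(len(trips))
    out = {}
    pos = 0
    for ind in individuals:
        for k in range(counts[ind]):
            out[trips[perm[pos + k]]] = ind
        pos += counts[ind]
    return out


def shuffle_trips(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Dataset-level trip shuffle (sex and trip order are ignored)."""
    if len(dataset.individuals) < 2:
        raise ValueError("shuffling needs at least 2 individuals")
    mapping = dict(
        dataset.fixes.drop_duplicates("trip_id")[["trip_id", "individual_id"]].to_numpy()
    )
    new_map = shuffle_assignment(mapping, rng)
    fixes = dataset.fixes.copy()
    fixes["individual_id"] = fixes["trip_id"].map(new_map)
    return Dataset(fixes, n_rejected=dataset.n_rejected, metadata=dict(dataset.metadata))


def null_test(
    points: pd.DataFrame,
    params: LocohParams,
    config: NullConfig,
    grid: GridSpec | None = None,
    strict: bool = False,
) -> tuple[MISIResult, NullDistribution]:
    """Permutation test of individual specialisation on a niche frame.

    Builds the shared grid once from the pooled cloud, computes the
    empirical MISI, then for each permutation set reassigns whole trips,
    recomputes every null individual's hypervolume on the same grid with the
    same ``a``, and takes the median of 1 - WIC/TNV with TNV fixed at its
    empirical value.  Returns the empirical result and the null
    distribution, with the 2.5%/97.5% null quantiles as the 95% CI band and

        p = #(null median > empirical median) / n_sets .
    """
    cols = coord_columns(points)
    cloud = points[cols].to_numpy(dtype=float)
    empirical = misi_from_points(points, params, grid=grid, strict=strict)
    grid = empirical.grid
    tnv = empirical.tnv

    if config.n_sets < 20:
        warnings.warn("fewer than 20 null sets: the 95% CI is unreliable", stacklevel=2)

    mapping = dict(points.drop_duplicates("trip_id")[["trip_id", "individual_id"]].to_numpy())
    trip_ids = points["trip_id"].to_numpy()
    pooled_checksum = _cloud_checksum(cloud)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_sets)
    medians = np.empty(config.n_sets)
    for s, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        new_map = shuffle_assignment(mapping, rng)
        # TNV invariance: the pooled point cloud is untouched by relabelling
        assert _cloud_checksum(cloud) == pooled_checksum
        null_ind = pd.Series(trip_ids).map(new_map).to_numpy()
        vals = []
        for ind in sorted(set(new_map.values()), key=str):
            sub = cloud[null_ind == ind]
            hv = individual_hypervolume(sub, params, grid, strict=strict)
            vals.append(1.0 - hv.volume / tnv if hv.volume > 0 else np.nan)
        medians[s] = np.nanmedian(vals)

    return empirical, summarise_null(medians, empirical.median_misi)


def summarise_null(medians: np.ndarray, empirical_median: float) -> NullDistribution:
    """One-sided summary: p is the proportion of null medians *strictly*
    greater than the empirical one (the add-one variant ``(b+1)/(n+1)``
    never reaches exactly zero); CI is the empirical 2.5%/97.5% band."""
    medians = np.asarray(medians, dtype=float)
    b = int((medians > empirical_median).sum())
    n = len(medians)
    return NullDistribution(
        medians=medians,
        empirical_median=float(empirical_median),
        ci_low=float(np.quantile(medians, 0.025)),
        ci_high=float(np.quantile(medians, 0.975)),
        p_value=b / n,
        p_value_add_one=(b + 1) / (n + 1),
    )


def _cloud_checksum(cloud: np.ndarray) -> int:
    return hash(cloud.tobytes())
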