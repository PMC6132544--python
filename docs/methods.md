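# Methods

## The index

For a population tracked over repeated foraging trips, each individual *i*
is represented by a cloud of points in a *d*-dimensional analysis space and
summarised by a niche hypervolume. The within-individual component `WIC_i`
is the volume of that hypervolume; the total niche volume `TNV` is the
volume of the union, over all individuals, of their local polytopes on one
shared grid. The Multidimensional Individual Specialisation Index is

    MISI_i = 1 − WIC_i / TNV,   0 ≤ MISI_i < 1,

a per-individual generalisation of the classical one-dimensional
within-individual/total niche width variance partition to volumes in
several dimensions. The population summary is the **median** MISI.
Tracking data measure *consistency* rather than physiological
specialisation; the index should be read accordingly.

Two analysis spaces are supported:

* **geographic** — projected (x, y) metres; MISI measures foraging site
  fidelity. Coordinates share a unit, so no standardisation is applied.
* **environmental** — one axis per environmental covariate (by default SST
  in °C, eddy kinetic energy, and depth in m, extracted at each foraging
  fix). EKE is log-transformed (natural log by default; the base is
  immaterial after z-scoring and a log10 switch exists). Every axis is then
  z-scored with the mean and *sample* (n−1) standard deviation pooled over
  all retained fixes of all individuals, so each dimension carries equal
  weight. Fixes with any missing covariate — including EKE ≤ 0, where the
  log is undefined — are dropped, with the dropped fraction reported,
  because the method needs a complete coordinate vector per point.

## Preprocessing assumptions

Fixes are grouped into trips, projected with a South-Pole Lambert azimuthal
equal-area projection (spherical formulation on the authalic radius
6 371 007.18 m; `lon_0 = 0`, any choice preserves areas), and linearly
interpolated in projected space to exact hourly fixes anchored at each
trip's first fix, so that point density is proportional to time spent.
Equal-area is the property that matters — cell counts must mean the same
volume everywhere; local *distances* are distorted by up to ~±5% at 54° S
(radial scale cos(c/2), transverse 1/cos(c/2)), which is accepted.

Transit is removed by **residence time**: for each fix, the summed time the
trajectory spends inside a circle of radius 45 km centred on it, counting
every re-entry, with segment/circle crossings located exactly on the linear
segments (an optional maximum-excursion cutoff reproduces the original
method's variant). The 45 km radius is the 45 km/h albatross glide speed
times the 1-h sampling interval; fixes with residence ≥ 25 000 s (the
antimode of the empirically bimodal residence distribution; boundary
inclusive, since shorter-than-threshold is transit) are foraging. Night
fixes are removed — solar elevation at each fix's own position and time
from the standard NOAA solar-position equations, sunrise/sunset zenith
90.833° — because drifting birds would otherwise masquerade as foragers;
polar day keeps everything, polar night drops everything. Where saltwater
immersion loggers exist, a fix is instead classed foraging iff at least one
10-min bout with > 3 s wet *starts* within ±30 min of it; bouts in the
window but none wet → transit, no bout coverage → unclassified.

## Hypervolume construction

Adaptive LoCoH: for focal point *p*, sort the other points of the same
individual by Euclidean distance (ties broken by ascending point index, for
reproducibility) and keep the longest prefix whose distances *sum* to ≤ a.
The polytope is the convex hull (Qhull) of the focal plus neighbours; a
full-dimensional polytope needs ≥ d+1 affinely independent points, so focal
points with fewer than d neighbours within budget — or degenerate (flat)
neighbourhoods — contribute nothing and are counted "ignored" (an outlier
filter). A stricter rule demanding d+1 *neighbours* is available
(`strict=True`); counts under both rules are always reported. The focal
point itself is a hull vertex and contributes 0 to the cumulative distance.

Volumes are measured on one shared regular grid: origin at the pooled
cloud's bounding-box minimum snapped down to a multiple of the grain, one
cell of margin; a cell is occupied iff its centroid lies inside at least
one polytope (half-space test on the Qhull facet inequalities, tolerance
1e-9, boundary counts as inside — deterministic and immune to grain-parity
artefacts); volume = occupied cells × grain^d. Exact coordinate ties make
polytopes flat, so environmental coordinates receive a uniform jitter of
±5e-5 **after** standardisation (where that magnitude is negligible — it
moves discretised volumes by far less than 1% at any sensible grain).

Defaults, all overridable: a = 400 km and grain = 25 km in geographic
space; a = 3 and grain = 0.125 in standardised environmental space.
Supported dimensions: 2–4. Neither `a` nor the grain is chosen
automatically: `diagnose_a` tabulates ignored-point fraction (monotone
non-increasing in a) and total volume (monotone non-decreasing) and plots
occupied cells over points for visual assessment; `diagnose_grain` refines
the grain until successive median-MISI change < 1% and flags the coarsest
stable grain. On sparse or strongly clustered clouds the grain must sit
below the cluster scale or thin local hulls fall between cell centroids and
volumes collapse to zero — the diagnostics make this visible.

## The permutation null model

"Null individuals" are built by dealing the real trips out uniformly at
random, whole and without replacement, conserving the empirical
per-individual trip-count multiset and ignoring sex and trip order. Keeping
trips intact preserves within-trip spatio-temporal autocorrelation, so the
null retains everything about the data except between-trip consistency of
identity. For each of `n_sets` shuffles (default 100) every null
individual's hypervolume is recomputed with the same `a` on the same grid,
and the median of `1 − WIC/TNV` is taken **with TNV held at its empirical
value**: the pooled point cloud — TNV's input — is unchanged by
relabelling (asserted on every run), whereas re-unioning grouping-dependent
local hulls would conflate niche size with grouping. One-sided p =
(# null medians > empirical median)/n_sets; an add-one estimator
(b+1)/(n+1) is available for users who want a nonzero lower bound. The 95%
band is the 2.5%/97.5% quantiles of the null medians. Sets draw from
independently spawned child generators of the master seed, so they are
reproducible and order-independent. Individuals whose hypervolume is empty
get an undefined MISI, excluded from medians with a warning.

## Synthetic data

The generator emulates the study design the method targets: a colony at
Bird Island, South Georgia; per individual, a small set of foraging patches
350–550 km out; per trip, a directed correlated random walk to a patch
(speed 45 ± 9 km/h, von Mises heading concentration 8), a dwell phase of
slow tortuous movement (stationary Ornstein–Uhlenbeck wobble, SD 15 km,
lag-1 correlation 0.7, 36 hourly fixes by default) and a walk home; hourly
fixes throughout, trips separated by 6–18 h of colony rest. With
probability `specialism` a trip revisits one of the individual's own
patches, otherwise it draws from the pooled patch list of all individuals —
so `specialism = 0` makes trips independent and identically distributed
across the population (exact trip-level exchangeability, the regime where
the test's size can be verified) and `specialism = 1` gives full site
fidelity. Dwell residence times exceed transit residence by construction,
and the residence threshold can be re-derived from the synthetic
distribution's antimode (Otsu's threshold on log residence) instead of
hard-coding 25 000 s. Synthetic rasters provide a poleward-cooling SST
field with weekly low-frequency noise, a positive patchy log-normal EKE
field, and a static bathymetry with a sharp shelf break, so the
neritic/oceanic contrast exists.

What the generator does **not** emulate: wind-driven flight costs and
drift, Argos location error, irregular/gappy duty cycles, memory-based
win-stay/lose-shift behaviour, and environmental fields with realistic
spatio-temporal covariance. Passing calibration on these data therefore
shows that the statistic and test behave correctly under the stated
sampling design, not that any particular field dataset will separate
specialists from generalists.

## Calibration experiments and problem sizes

The statistical checks run at deliberately scaled-down sizes chosen once:

* **Type-I error** — 200 generalist populations (5 individuals × 4 trips,
  10 dwell fixes/trip), 25 null sets each, a = 400 km, grain 15 km (below
  the 15-km dwell spread, per the grain diagnostic). Exchangeability is
  scale-free, so the smallest population suffices. With 25 null sets and
  the strictly-greater convention, p < 0.05 requires the empirical median
  to rank in the top 2 of 26 exchangeable values: the exact achievable
  level is 2/26 ≈ 0.077, and the observed rejection rate is compared to
  that level by an exact binomial test rather than to 0.05 itself.
* **Power** — 60 specialist populations at the generator's default scale
  (6 × 8); expected ≥ 80% of p ≤ 0.05.
* **Specialism sweep** — median MISI over 50 replicates at specialism 0,
  0.25, 0.5, 0.75, 1 (6 × 8 scale), expected Spearman ≥ 0.9 against the
  sweep — the parameter-recovery check for the generator/index pair.

`scripts/acceptance.py` recomputes exactly these quantities (plus one
full-pipeline specialist run including interpolation and residence/daylight
filtering) from the `--seed` argument alone and writes them as JSON;
`tests/test_acceptance.py` asserts them alongside the geometry oracles
(shoelace areas to 1e-9 relative, the 3-D unit-simplex volume 1/6,
grid-versus-Monte-Carlo volume agreement within 2%) and the structural
invariants (MISI bounds, WIC ≤ TNV, cell-set nestedness in `a`, union
subadditivity, pooled-cloud invariance under shuffling).

## Numerical choices and limitations

* Degenerate inputs: trips shorter than one interval pass through
  interpolation unchanged with a warning; a constant environmental variable
  raises a degenerate-dimension error; identical points yield empty
  hypervolumes (all ignored) rather than crashing; TNV = 0 raises.
* Nearest-date raster lookup ties break to the earlier layer; depth is
  static (no date matching).
* The residence radius is applied in projected metres; at trip scale the
  difference from great-circle distance is negligible relative to the
  45-km radius. Sunrise/sunset is evaluated at each fix's own position.
* No Argos-class or speed pre-filtering is applied by default (tracks are
  assumed already usable); `read_tracks` exposes a `prefilter` hook.
* Complexity is O(n²) per individual for neighbour search and residence
  time, and proportional to polytope-bounding-box cell counts for
  occupancy; 2–4 dimensions and a few thousand points per population are
  comfortable on one CPU. Very fine grains in 4-D are memory-hungry.
* k-nearest-neighbour and fixed-radius LoCoH variants are deliberately not
  implemented; the adaptive variant is the method here.
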