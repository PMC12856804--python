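# Methods

This note documents the statistical procedures `pelagos` implements, the
defaults and the reasoning behind them, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Geodesy

All distances are haversine great circles on a sphere of radius
6371.0088 km (IUGG mean radius); azimuths are forward bearings clockwise
from true north in [0, 360). Kernel estimation needs a metric plane, so
fixes are projected with a spherical azimuthal-equidistant projection
centred between the two colonies: distances and azimuths from the centre
are preserved exactly, and at the foraging scales involved (≤ ~2500 km
from the centre) the distortion of distances between arbitrary point pairs
is below ~2 %, far inside the 60–105 km kernel bandwidths. The inverse
projection is closed-form; round-trip error is < 1 m (tested).

The bearing of a point coincident with its reference is undefined and
raises an error rather than returning an arbitrary 0°, which would bias
circular means silently.

## Track processing

**Speed filter.** Fixes implying travel above 80 km/h are removed by a
sequential root-removal pass per bird: each fix is tested against the
previous *kept* fix. A single displaced outlier is removed by itself;
pairwise deletion would also discard an innocent neighbour. Duplicate
timestamps are a hard error.

**Regularization.** Tracks are resampled to clock-hour marks by linear
interpolation between the bracketing raw fixes (short-way-round in
longitude). Raw gaps longer than 12 h (default) are not bridged;
interpolating across a long gap invents a straight transit that never
happened.

**Trip splitting.** A trip runs from the last fix inside the 5-km colony
buffer before an excursion to the first fix back inside. Excursions
shorter than 6 h are treated as near-colony loafing and dropped — the
shortest real stage-mean trips are ~3 days, so 6 h is conservative. A
terminal excursion with no return is kept but flagged incomplete, and
incomplete trips are excluded from summary statistics (they censor
duration, distance and range downward).

**Stage inference.** Stages are assigned by calendar overlap with the
breeding windows (incubation 9 Jan–29 Mar, brood guard 2 Mar–18 Apr,
postguard 5 Apr–18 Aug; half-open at UTC midnight, last day included).
Where two windows overlap, a trip followed by more than 12 h of colony
attendance goes to the earlier stage: incubation and brood-guard trips end
in a long nest shift, postguard trips end in a brief feed. *Limitation:*
in the March overlap both incubation and brood-guard trips are followed by
long shifts, so the attendance rule cannot separate them and early-March
brood-guard trips are assigned to incubation. This ambiguity is inherent
to the rule; per-bird chronology would be needed to resolve it.

## Utilization distributions and the segregation test

A trip's UD is an isotropic bivariate-Gaussian kernel estimate on a 10-km
grid, with kernel SD equal to the stage bandwidth (105 km incubation and
postguard, 60 km brood guard — larger-ranging stages get heavier
smoothing). Numerically the fixes are binned to the raster and convolved
with the kernel (truncated at 6 SD, renormalized); with bandwidths ≥ 6
cells the half-cell binning error is negligible — the mass inside the
closed-form half-mass radius 1.1774 h of a single fix is reproduced to
±0.02. The shared grid covers both colonies' fixes padded by three
bandwidths, so no kernel mass is clipped.

The population UD is the **unweighted mean of per-trip UDs**: the
randomization test reassigns trips, so the trip must also be the
aggregation unit, otherwise the observed statistic and its null would be
computed under different weightings. Birds contributing more trips
contribute more weight; this matches the randomization design.

Isopleths (50 % core, 95 % home range) are the minimal set of
highest-density cells whose cumulative mass reaches the level, ties broken
by stable cell index; the contained mass exceeds the level by at most one
cell mass, and removing any selected cell drops below the level
(tested properties).

Bhattacharyya affinity is `Σ √(p_A p_B)` over shared cells (1 identical,
0 disjoint). The segregation test reassigns trips to colonies at random,
preserving group sizes, recomputing the population UDs and BA each time
(per-trip UDs are computed once and reused). The p-value is the plain
proportion of null affinities *below* the observed one; the (r+1)/(n+1)
permutation variant is available via `plus_one=True`. Type-I error at
α = 0.05 is calibrated within [0.02, 0.08] over 200 true-null replicates
(tested). For core/home-range-restricted comparisons each population UD is
renormalized within its own isopleth mask before BA — the restriction
procedure is an interpretation, since only the isopleth levels themselves
are standard.

**Representativeness.** For subsample sizes s = 1..N−1, random trip
subsets are drawn and the mean fraction of out-of-sample fixes inside the
subset's 50 % isopleth recorded; a saturating hyperbola y = a·s/(b+s) is
fitted by least squares and the score is the fitted inclusion at N as a
percentage of the asymptote a (capped at 100). The hyperbola is a standard
saturating form for inclusion-vs-effort curves; with N = 2 the curve is
unidentifiable and the raw inclusion is returned flagged low-confidence.

## Wind and circular statistics

Wind direction uses the meteorological **from** convention throughout
(southwesterly = from 225°). Reanalysis u/v are *toward* components, hence
`from = (atan2(u, v)·180/π + 180) mod 360`. Circular SD is `√(−2 ln R)`
converted to degrees; a vanishing resultant (antipodal data) flags the
mean as undefined (NaN) rather than picking a direction.

Watson's two-sample U² is the rotation-invariant Cramér–von Mises
statistic on the circle, computed from the pooled ECDF difference
evaluated once per distinct value weighted by multiplicity (so fully tied
samples give exactly 0). p-values come from label permutation by default
(seeded), or from asymptotic critical-value bands (0.152/0.187/0.268/0.385
for 0.10/0.05/0.01/0.001) reported in the "p > 0.10" style.

Circular regressions model the response as von Mises with mean direction
`μ + 2·atan(η)`, where η is `β_c cos x + β_s sin x` for a circular
predictor or `β·t` (t centred and scaled) for a scalar one. The tangent
link keeps the angular offset in (−π, π). Estimation is maximum
likelihood (L-BFGS-B, `log I₀` via the exponentially scaled Bessel
function for stability; ftol 1e−12), started from the least-squares fit of
the embedded residual direction plus a zero-coefficient restart.
Per-component significance is a likelihood-ratio χ²₁ test against the
model with that component removed. Null p-values are approximately uniform
at n = 30 (slightly anti-conservative, as usual for LRTs at small n);
power against a response tracking the predictor is essentially 1
(both tested).

## Fisheries overlap

Time in a 1° cell is the count of regularized hourly fixes of all birds of
a colony within the stage window (fix counts are proportional to time only
after regularization, hence the precondition). Cells are half-open
[k, k+1) in both coordinates; boundary fixes go to the lower-left cell.
The overlap index is `Σ share(cell) · hours(cell)`, computed per colony,
stage, gear type and flag state; 'all fishing' rows reconcile exactly with
the disaggregation, and the index is linear in effort hours. The colony —
not the bird — is the normalization unit, so birds with more fixes weight
the share grid; and because stage windows differ in length and overlap in
the calendar, indices compare between colonies but not between stages (the
caveat is attached to every output table). The index measures co-occurrence
exposure, not bycatch rate.

## Habitat preparation

Pseudoabsences are drawn uniformly **by area** on the spherical cap of the
colony's maximum observed foraging range (angular distance sampled from
the cap's area measure, azimuth uniform), three per presence. Eddy kinetic
energy and chlorophyll-a are log₁₀-transformed, SST standard deviation
square-root-transformed; non-positive values in a log column are an error.
Collinearity screening walks covariates from most to least predictive and
keeps each only if |Pearson r| ≤ 0.6 against everything already kept —
rank-priority processing makes the result independent of column order.
AUC is the tie-averaged rank (Mann–Whitney) estimator, equal to
brute-force pair enumeration (tested), with qualitative bands 0.5–0.7
poor, 0.7–0.9 reasonable, > 0.9 very good. Cross-validation folds are
grouped by bird so an individual never appears on both sides of a fold.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:
two colonies 42 km apart at the real study coordinates; hourly fixes;
three-phase trips (directed outbound leg along a von Mises mixture
bearing, slow tortuous foraging, homing) with log-normal durations of
median 280 h (incubation), 70 h (brood guard), 160 h (postguard) and
outbound speeds of 30 ± 8 km/h, giving foraging ranges of hundreds to
~2000 km; at-colony attendance between trips (long after incubation and
brood-guard trips, short after postguard ones, which is what stage
inference keys on); optional isolated outlier fixes displaced 250–400 km
(guaranteed to violate the 80 km/h ceiling, with labels kept as ground
truth); von Mises southwesterly winds; and fishing-effort hotspots with
Gaussian within-radius decay conserving each hour budget exactly.

It does **not** emulate: albatross energetics or wind-dependent flight,
area-restricted search behaviour, ARGOS error ellipses, serial
autocorrelation in habitat covariates along tracks, or vessel behaviour.
Passing tests therefore demonstrate that the estimators recover imposed
structure of this idealized kind — bearing-mixture segregation, known trip
counts, labelled outliers, budgeted effort — not that they are robust to
every pathology of real tracking data.

Scaled-down conditions for the simulation experiments (type-I calibration,
power, recovery) use single-stage configs of 50–100 trips with median 24-h
trips at 20 km/h and the 60-km brood-guard bandwidth, and 200
randomization iterations instead of 1000; these sizes give stable
calibration estimates across hundreds of replicates while keeping the
whole suite a few minutes long. The acceptance script runs the full-scale
defaults with 1000 iterations.

## Known limitations

- The March incubation/brood-guard ambiguity described above.
- Binned KDE assumes bandwidth ≫ cell size; for bandwidths below ~2 cells
  use a finer grid.
- The representativeness asymptote model is one reasonable saturating
  form; the score is insensitive to the choice near saturation but not at
  small N.
- The circular-regression link is single-harmonic; responses with
  bimodal dependence on the predictor need a richer mean function.
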