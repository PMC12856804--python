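# pelagos

Spatial segregation and fisheries-overlap analysis for colony-based
(central-place foraging) seabird tracking studies.

When two colonies of a wide-ranging seabird sit only tens of kilometres
apart, their at-sea foraging distributions may still segregate — and the
two populations can then face very different exposure to fishing fleets.
`pelagos` implements the full analysis chain for such a two-colony study,
for movement ecologists and conservation practitioners working with
GPS/PTT tracking data:

- **Track processing** — plausibility filtering of fixes (travel speeds
  > 80 km/h removed by sequential root-removal), regularization to hourly
  intervals, segmentation into colony-anchored trips, breeding-stage
  inference from the calendar and colony attendance (> 12 h at the nest
  after incubation and brood-guard trips), and per-trip summary metrics
  (duration, path length, foraging range, bearing to the farthest point).
- **Utilization distributions** — per-trip kernel UDs (Gaussian kernel,
  stage-specific bandwidth *h* = 105 km for incubation/postguard, 60 km
  for brood guard, on a 10-km grid in an azimuthal-equidistant plane),
  population UDs as unweighted trip means, and 50 % (core) / 95 % (home
  range) isopleths.
- **Segregation test** — Bhattacharyya affinity
  `BA = Σ_cells √(p_A · p_B)` between population UDs, with a trip
  randomization test: trips are reassigned to colonies at random (group
  sizes preserved), BA recomputed each time, and
  `p = #{BA_null < BA_obs} / n_iter`.
- **Wind circular statistics** — meteorological from-direction conventions,
  vector means and circular SD `√(−2 ln R)`, Watson's two-sample U² test
  of homogeneity (permutation or critical-value bands), and von Mises
  circular–circular / circular–linear regressions with a `2·atan` link.
- **Fisheries overlap** — per 1° cell, the proportion of colony time is
  multiplied by hours fished; summed over cells this gives a relative
  exposure index per colony, stage, gear type and flag state (not a
  bycatch rate).
- **Habitat-model preparation** — 3:1 pseudoabsences sampled uniformly by
  area within the maximum foraging range, log₁₀/√ covariate transforms,
  |r| > 0.6 collinearity screening by predictive rank, rank-based AUC with
  poor / reasonable / very good bands, and bird-grouped CV folds.
- **Synthetic data** — a seeded generator producing two-colony tracking
  data (three-phase correlated-random-walk trips with imposable east/west
  departure-bearing segregation), winds, clustered fishing effort and
  covariate fields, so the whole pipeline is testable without any
  external download.

## Worked example

```python
import numpy as np
from pelagos import pipeline, synthetic
from pelagos.tracks import Colony

bird = Colony("BirdIsland", -54.000, -38.050)
prion = Colony("PrionIsland", -54.0333, -37.4167)

# two colonies with opposed (east/west) departure-bearing distributions
cfg = synthetic.compact_config(separation_deg=180.0, trips_per_colony=50)
ts = synthetic.simulate_tracks(cfg, seed=42)

fixes = pipeline.clean_tracks(ts.fixes)          # speed filter + hourly grid
windows = cfg.stage_windows()
trips_a = pipeline.colony_trips(fixes, bird, stage_windows=windows)
trips_b = pipeline.colony_trips(fixes, prion, stage_windows=windows)

seg = pipeline.stage_segregation(
    trips_a, trips_b, "brood_guard", bird, prion, n_iter=1000, seed=1
)
print(f"observed BA = {seg.result.observed_ba:.4f}, p = {seg.result.p_value:.3f}")
```

Output:

```
observed BA = 0.5937, p = 0.000
```

The observed Bhattacharyya affinity of 0.59 says the two population UDs
share only part of their mass; `p = 0.000` means none of the 1000 trip
randomizations produced an affinity as low — the imposed east/west
segregation is recovered as highly significant. With
`separation_deg=0.0` the affinity rises towards 1 and the p-value becomes
non-significant.

The same analyses are available from the shell:

```bash
pelagos simulate --seed 1 --out-dir sim/
pelagos segregation --tracks sim/tracks.csv --stage incubation --n-iter 1000 --seed 1
pelagos overlap --tracks sim/tracks.csv --effort sim/effort.csv --by gear --out overlap.csv
```

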