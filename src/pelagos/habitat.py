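"""Data preparation and evaluation scaffolding for habitat models.

Habitat (presence/background) models contrast tracked locations with
pseudoabsences sampled uniformly by area within the colony's maximum
foraging distance.  This module generates the pseudoabsences, applies the
standard covariate transforms, screens collinear covariates, and scores
predictions with a rank-based AUC; the smoother fitting itself is left to
general-purpose statistical machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pelagos.geo import EARTH_RADIUS_KM, destination
from pelagos.tracks import Colony

#: default transform assignments: spread-improving transforms for skewed
#: oceanographic covariates
LOG10_COVARIATES = ("eddy_kinetic_energy", "chlorophyll_a")
SQRT_COVARIATES = ("sst_sd",)

AUC_BANDS = ((0.9, "very good"), (0.7, "reasonable"), (0.5, "poor"))


def pseudoabsences(
    presences: pd.DataFrame,
    colony: Colony,
    max_range_km: float,
    ratio: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample background points uniformly by area within the foraging range.

    Draws ``ratio`` pseudoabsences per presence row, uniformly over the
    spherical cap of radius ``max_range_km`` centred on the colony (the
    angular distance is drawn from the cap's area measure, so equal-area
    annuli receive equal expected counts).  Returns the presences (label
    ``presence``) concatenated with the generated points (label
    ``pseudoabsence``); deterministic given ``seed``.
    """
    if max_range_km <= 0:
        raise ValueError("max_range_km must be positive")
    n = ratio * len(presences)
    rng = np.random.default_rng(seed)
    sigma_max = max_range_km / EARTH_RADIUS_KM
    u = rng.random(n)
    cos_sigma = 1.0 - u * (1.0 - np.cos(sigma_max))
    sigma = np.arccos(np.clip(cos_sigma, -1.0, 1.0))
    azimuth = rng.random(n) * 360.0
    lat, lon = destination(colony.lat, colony.lon, azimuth, sigma * EARTH_RADIUS_KM)
    pres = presences.copy()
    pres["label"] = "presence"
    absn = pd.DataFrame({"lat": lat, "lon": lon})
    absn["label"] = "pseudoabsence"
    out = pd.concat([pres, absn], ignore_index=True)
    out["colony"] = colony.name
    return out


def transform_covariates(
    points: pd.DataFrame,
    log10_cols: tuple[str, ...] = LOG10_COVARIATES,
    sqrt_cols: tuple[str, ...] = SQRT_COVARIATES,
) -> pd.DataFrame:
    """Apply log10 / square-root transforms to the named covariates.

    Non-positive values in a log10 column are a hard error (they indicate
    an upstream extraction problem, not data to be silently dropped).
    """
    out = points.copy()
    for col in log10_cols:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            bad = np.flatnonzero(vals <= 0)[:10]
            raise ValueError(
                f"non-positive values in log10 covariate {col!r} at rows {bad.tolist()}"
            )
        out[col] = np.log10(vals)
    for col in sqrt_cols:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            bad = np.flatnonzero(vals < 0)[:10]
            raise ValueError(
                f"negative values in sqrt covariate {col!r} at rows {bad.tolist()}"
            )
        out[col] = np.sqrt(vals)
    return out


def collinearity_filter(
    covariates: pd.DataFrame,
    predictive_rank: list[str],
    r_threshold: float = 0.6,
) -> list[str]:
    """Greedy collinearity screen: walk the covariates from the most to the
    least predictive, keeping each one only if its absolute Pearson r with
    every already-kept covariate is at or below ``r_threshold``.  The
    rank-priority order makes the result independent of column order."""
    missing = [c for c in predictive_rank if c not in covariates.columns]
    if missing:
        raise ValueError(f"ranked covariates not in table: {missing}")
    corr = covariates[predictive_rank].corr(method="pearson").abs()
    kept: list[str] = []
    for cov in predictive_rank:
        if all(corr.loc[cov, k] <= r_threshold for k in kept):
            kept.append(cov)
    return kept


def auc(labels, scores) -> tuple[float, str]:
    """Rank-based (tie-averaged) AUC with a qualitative band.

    ``labels`` are boolean/0-1 with 1 = presence.  The AUC equals the
    probability that a random presence outscores a random absence (ties
    counting half), i.e. the Mann-Whitney statistic.  Bands follow the
    conventional cut-points: 0.5-0.7 poor, 0.7-0.9 reasonable, >0.9 very
    good.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = stats.rankdata(s)
    value = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    band = "worse than chance"
    for cut, name in AUC_BANDS:
        if value > cut:
            band = name
            break
    else:
        if value >= 0.5:
            band = "poor"
    return float(value), band


def grouped_folds(
    bird_ids, n_folds: int = 5, seed: int | None = None
) -> pd.Series:
    """Cross-validation fold ids grouped by bird, so no individual appears
    in both the training and the held-out side of a fold."""
    bird_ids = pd.Series(bird_ids)
    birds = bird_ids.dropna().unique()
    if n_folds < 2 or n_folds > len(birds):
        raise ValueError("n_folds must be between 2 and the number of birds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(birds)
    assignment = {b: i % n_folds for i, b in enumerate(shuffled)}
    return bird_ids.map(assignment)
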