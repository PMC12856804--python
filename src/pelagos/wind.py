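"""Circular statistics for wind at departure and departure bearings.

Wind direction follows the meteorological "from" convention throughout: a
southwesterly wind blows FROM 225 deg.  Note that reanalysis u/v winds are
"toward" components (u east-positive, v north-positive), hence the 180 deg
shift in :func:`uv_to_wind`.  All angles at the interface are degrees in
[0, 360); internal computation is in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from pelagos.geo import initial_bearing


def uv_to_wind(u, v):
    """(u, v) wind components (m/s, toward) -> (speed, from-direction deg)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    from_dir = np.mod(np.degrees(np.arctan2(u, v)) + 180.0, 360.0)
    if speed.ndim == 0:
        return float(speed), float(from_dir)
    return speed, from_dir


def wind_to_uv(speed, from_direction_deg):
    """Inverse of :func:`uv_to_wind`."""
    speed = np.asarray(speed, dtype=float)
    theta = np.radians(np.asarray(from_direction_deg, dtype=float))
    u = -speed * np.sin(theta)
    v = -speed * np.cos(theta)
    if u.ndim == 0:
        return float(u), float(v)
    return u, v


@dataclass(frozen=True)
class CircularSummary:
    """Vector-mean direction, circular SD (sqrt(-2 ln R), in degrees),
    mean resultant length R, and sample size.  ``mean_deg`` is NaN when the
    resultant length vanishes (e.g. antipodal pairs): the mean direction is
    then undefined."""

    mean_deg: float
    sd_deg: float
    resultant_length: float
    n: int


def circular_mean_sd(angles_deg) -> CircularSummary:
    a = np.radians(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    if a.size == 0:
        raise ValueError("need at least one angle")
    C = np.cos(a).mean()
    S = np.sin(a).mean()
    R = float(np.hypot(C, S))
    if R < 1e-12:
        return CircularSummary(float("nan"), float("inf"), R, a.size)
    mean = np.degrees(np.arctan2(S, C)) % 360.0
    sd = np.degrees(np.sqrt(-2.0 * np.log(R)))
    return CircularSummary(float(mean), float(sd), R, a.size)


#: Upper critical values of the two-sample Watson U^2 statistic
#: (asymptotic), used for banded p-value reporting.
_WATSON_CRIT = [(0.385, 0.001), (0.268, 0.01), (0.187, 0.05), (0.152, 0.10)]


@dataclass(frozen=True)
class WatsonResult:
    u2: float
    p_value: float | None
    p_band: str
    method: str
    n_perm: int | None = None


def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Watson U^2 from the pooled empirical CDF difference.

    Ties are handled by evaluating the CDF difference once per distinct
    pooled value, weighted by its multiplicity, so identical samples give
    exactly 0.
    """
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    is_a = np.zeros(N, dtype=bool)
    is_a[:n] = True
    order = np.argsort(pooled, kind="stable")
    v = pooled[order]
    is_a = is_a[order]
    d = np.cumsum(np.where(is_a, 1.0 / n, -1.0 / m))
    last = np.r_[np.flatnonzero(np.diff(v) != 0), N - 1]
    mult = np.diff(np.r_[-1, last]).astype(float)
    dj = d[last]
    dbar = np.sum(mult * dj) / N
    return float(n * m / N**2 * np.sum(mult * (dj - dbar) ** 2))


def watson_u2(
    angles_a_deg,
    angles_b_deg,
    p_method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> WatsonResult:
    """Watson's two-sample U^2 test of homogeneity for circular data.

    The statistic is the rotation-invariant Cramer-von Mises distance
    between the two samples' empirical distributions on the circle.  The
    p-value comes either from a label permutation (``p_method="permutation"``,
    exact up to Monte Carlo error) or from asymptotic critical-value bands
    (``p_method="table"``, reported in the "p > 0.10" style).
    """
    a = np.mod(np.atleast_1d(np.asarray(angles_a_deg, dtype=float)), 360.0)
    b = np.mod(np.atleast_1d(np.asarray(angles_b_deg, dtype=float)), 360.0)
    if a.size < 8 or b.size < 8:
        raise ValueError("watson_u2 requires at least 8 angles per sample")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < pooled.size:
        warnings.warn("ties between angles; consider jittering", stacklevel=2)
    u2 = _watson_u2_stat(a, b)
    band = "p > 0.10"
    for crit, alpha in _WATSON_CRIT:
        if u2 >= crit:
            band = f"p < {alpha:g}"
            break
    if p_method == "table":
        return WatsonResult(u2, None, band, "table")
    if p_method != "permutation":
        raise ValueError("p_method must be 'permutation' or 'table'")
    rng = np.random.default_rng(seed)
    n = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(perm[:n], perm[n:]) >= u2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return WatsonResult(u2, float(p), band, "permutation", n_perm)


def departure_bearing(trip_fixes, window_h: float = 3.0) -> float:
    """Circular mean of step headings over the first ``window_h`` hours at
    sea.  ``trip_fixes`` is a DataFrame with timestamp/lat/lon (a
    :class:`pelagos.tracks.Trip` may be passed directly)."""
    f = getattr(trip_fixes, "fixes", trip_fixes)
    t = f["timestamp"]
    lat = f["lat"].to_numpy()
    lon = f["lon"].to_numpy()
    if len(f) < 2:
        raise ValueError("need at least two fixes")
    hours = (t - t.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    # steps whose start falls inside the window; always keep the first step
    sel = np.where(hours[:-1] < window_h)[0]
    if sel.size == 0:
        sel = np.array([0])
    headings = []
    for i in sel:
        if lat[i] == lat[i + 1] and lon[i] == lon[i + 1]:
            continue
        headings.append(initial_bearing(lat[i], lon[i], lat[i + 1], lon[i + 1]))
    if not headings:
        raise ValueError("no displacement in departure window")
    return circular_mean_sd(headings).mean_deg


# ---------------------------------------------------------------------------
# von Mises regression with circular or linear covariates


@dataclass(frozen=True)
class CircRegressionFit:
    mu_deg: float
    coefficients: dict[str, float]
    kappa: float
    loglik: float
    p_values: dict[str, float]
    n: int


def _vm_negloglik(params, theta, design):
    mu = params[0]
    kappa = np.exp(params[-1])
    beta = params[1:-1]
    mean = mu + 2.0 * np.arctan(design @ beta) if beta.size else np.full_like(theta, mu)
    # log I0(kappa) = log i0e(kappa) + kappa, numerically stable
    return -np.sum(kappa * np.cos(theta - mean)) + theta.size * (
        np.log(2 * np.pi) + np.log(special.i0e(kappa)) + kappa
    )


def _fit_vm(theta, design):
    """Maximize the von Mises likelihood; returns (params, loglik)."""
    summ = circular_mean_sd(np.degrees(theta))
    mu0 = np.radians(summ.mean_deg) if np.isfinite(summ.mean_deg) else 0.0
    R = min(summ.resultant_length, 0.999)
    # Banerjee et al. approximation of A^{-1}(R)
    kappa0 = max(R * (2 - R**2) / max(1 - R**2, 1e-6), 1e-3)
    k = design.shape[1]
    beta0 = np.zeros(k)
    if k:
        # least squares of the embedded residual direction on the covariates
        resid = np.sin(theta - mu0)
        beta0, *_ = np.linalg.lstsq(design, resid, rcond=None)
    x0 = np.concatenate([[mu0], beta0, [np.log(kappa0)]])
    best = None
    for start in (x0, np.concatenate([[mu0], np.zeros(k), [np.log(kappa0)]])):
        res = optimize.minimize(
            _vm_negloglik,
            start,
            args=(theta, design),
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun


def _lrt_p(ll_full, ll_reduced, df=1):
    lrt = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lrt, df))


def circ_circ_regression(response_deg, predictor_deg) -> CircRegressionFit:
    """Regression of a circular response on a circular predictor.

    The response is modelled as von Mises with mean direction
    mu + 2*atan(b_c cos x + b_s sin x); the tangent link keeps the angular
    offset in (-pi, pi).  Component significance is assessed by
    likelihood-ratio tests against the model with that component removed.
    """
    theta = np.radians(np.atleast_1d(np.asarray(response_deg, dtype=float)))
    x = np.radians(np.atleast_1d(np.asarray(predictor_deg, dtype=float)))
    if theta.size == 0:
        raise ValueError("empty response")
    if theta.size != x.size:
        raise ValueError("response and predictor lengths differ")
    if theta.size < 5:
        raise ValueError("too few observations to identify the model")
    design = np.column_stack([np.cos(x), np.sin(x)])
    params, ll_full = _fit_vm(theta, design)
    _, ll_no_cos = _fit_vm(theta, design[:, [1]])
    _, ll_no_sin = _fit_vm(theta, design[:, [0]])
    return CircRegressionFit(
        mu_deg=float(np.degrees(params[0]) % 360.0),
        coefficients={"cos": float(params[1]), "sin": float(params[2])},
        kappa=float(np.exp(params[-1])),
        loglik=float(ll_full),
        p_values={"cos": _lrt_p(ll_full, ll_no_cos), "sin": _lrt_p(ll_full, ll_no_sin)},
        n=int(theta.size),
    )


def circ_lin_regression(response_deg, predictor) -> CircRegressionFit:
    """Regression of a circular response on a scalar predictor, with mean
    direction mu + 2*atan(b * t)."""
    theta = np.radians(np.atleast_1d(np.asarray(response_deg, dtype=float)))
    t = np.atleast_1d(np.asarray(predictor, dtype=float))
    if theta.size == 0:
        raise ValueError("empty response")
    if theta.size != t.size:
        raise ValueError("response and predictor lengths differ")
    if theta.size < 5:
        raise ValueError("too few observations to identify the model")
    # centre and scale the covariate for a stable tangent link
    t_c = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    design = t_c[:, None]
    params, ll_full = _fit_vm(theta, design)
    _, ll_null = _fit_vm(theta, np.empty((theta.size, 0)))
    return CircRegressionFit(
        mu_deg=float(np.degrees(params[0]) % 360.0),
        coefficients={"slope": float(params[1])},
        kappa=float(np.exp(params[-1])),
        loglik=float(ll_full),
        p_values={"slope": _lrt_p(ll_full, ll_null)},
        n=int(theta.size),
    )
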