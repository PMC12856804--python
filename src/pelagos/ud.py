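"""Kernel utilization distributions (UDs), isopleth core areas,
Bhattacharyya affinity, and the trip-randomization segregation test.

A UD is a discrete probability surface on a planar grid (cells sum to 1)
obtained by Gaussian kernel smoothing of a trip's fixes after projecting
them to a local azimuthal-equidistant plane.  Population-level UDs are
unweighted means of per-trip UDs, mirroring the randomization unit of the
segregation test (trips, not birds, are relabelled).

The smoothing bandwidth is stage-specific: 105 km for incubation and
postguard trips (long-ranging, up to ~2000 km from the colony) and 60 km
for the shorter brood-guard trips, on a 10-km grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

#: stage -> Gaussian kernel SD in km
DEFAULT_BANDWIDTH_KM: dict[str, float] = {
    "incubation": 105.0,
    "brood_guard": 60.0,
    "postguard": 105.0,
}
DEFAULT_CELL_KM = 10.0


@dataclass(frozen=True)
class SmoothingSpec:
    """Stage-keyed kernel bandwidths (km) and grid cell size (km)."""

    bandwidth_km: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BANDWIDTH_KM)
    )
    cell_km: float = DEFAULT_CELL_KM

    def __post_init__(self):
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if any(b <= 0 for b in self.bandwidth_km.values()):
            raise ValueError("bandwidths must be positive")

    def for_stage(self, stage: str) -> float:
        return self.bandwidth_km[stage]


@dataclass(frozen=True)
class GridSpec:
    """Planar raster: origin at the lower-left cell edge, row-major (y, x)."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell_km: float

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xc = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        yc = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        return xc, yc

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_km).astype(int)
        return ix, iy

    def contains(self, x, y) -> np.ndarray:
        ix, iy = self.index_of(x, y)
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)


@dataclass
class UDGrid:
    """Discrete utilization distribution: ``pmf`` has shape (ny, nx), is
    non-negative and sums to 1."""

    grid: GridSpec
    pmf: np.ndarray

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("pmf shape does not match grid")
        if np.any(self.pmf < 0):
            raise ValueError("pmf has negative mass")
        s = self.pmf.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"pmf sums to {s}, not 1")


@dataclass(frozen=True)
class IsoplethMask:
    """Minimal top-density cell set whose cumulative mass reaches ``level``."""

    level: float
    mask: np.ndarray
    contained_mass: float


@dataclass(frozen=True)
class OverlapResult:
    observed_ba: float
    null_ba: np.ndarray
    p_value: float
    n_iter: int
    seed: int | None
    isopleth_level: float | None = None


def make_grid(
    x, y, bandwidth_km: float, cell_km: float = DEFAULT_CELL_KM, pad_bandwidths: float = 3.0
) -> GridSpec:
    """Grid covering the points padded by ``pad_bandwidths`` kernel SDs,
    with the origin snapped to the cell lattice through (0, 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pad = pad_bandwidths * bandwidth_km
    x0 = np.floor((x.min() - pad) / cell_km) * cell_km
    y0 = np.floor((y.min() - pad) / cell_km) * cell_km
    nx = int(np.ceil((x.max() + pad - x0) / cell_km))
    ny = int(np.ceil((y.max() + pad - y0) / cell_km))
    return GridSpec(x0=float(x0), y0=float(y0), nx=nx, ny=ny, cell_km=cell_km)


def _expand_grid(grid: GridSpec, x, y, margin_km: float) -> GridSpec:
    c = grid.cell_km
    x0 = min(grid.x0, np.floor((np.min(x) - margin_km) / c) * c)
    y0 = min(grid.y0, np.floor((np.min(y) - margin_km) / c) * c)
    x1 = max(grid.x0 + grid.nx * c, np.max(x) + margin_km)
    y1 = max(grid.y0 + grid.ny * c, np.max(y) + margin_km)
    return GridSpec(
        x0=float(x0),
        y0=float(y0),
        nx=int(np.ceil((x1 - x0) / c)),
        ny=int(np.ceil((y1 - y0) / c)),
        cell_km=c,
    )


def kde_ud(x, y, bandwidth_km: float, grid: GridSpec) -> UDGrid:
    """Gaussian-kernel UD of one trip's planar fixes on ``grid``.

    Fixes are binned to the 10-km raster and convolved with an isotropic
    Gaussian of SD ``bandwidth_km``; with bandwidths of 60-105 km the
    half-cell binning error is negligible.  If the grid does not cover all
    fixes plus three bandwidths it is expanded (with a warning), so callers
    sharing a grid across trips should build it from the pooled fixes.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.size == 0:
        raise ValueError("kde_ud requires at least one fix")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    margin = 3.0 * bandwidth_km
    c = grid.cell_km
    if (
        np.min(x) - margin < grid.x0
        or np.min(y) - margin < grid.y0
        or np.max(x) + margin > grid.x0 + grid.nx * c
        or np.max(y) + margin > grid.y0 + grid.ny * c
    ):
        warnings.warn("grid extent does not cover fixes + 3 bandwidths; expanding",
                      stacklevel=2)
        grid = _expand_grid(grid, x, y, margin)
    ix, iy = grid.index_of(x, y)
    counts = np.zeros((grid.ny, grid.nx))
    np.add.at(counts, (iy, ix), 1.0)
    sigma_cells = bandwidth_km / c
    pmf = ndimage.gaussian_filter(counts, sigma=sigma_cells, mode="constant", truncate=6.0)
    pmf /= pmf.sum()
    return UDGrid(grid=grid, pmf=pmf)


def population_ud(uds: list[UDGrid]) -> UDGrid:
    """Unweighted mean of per-trip UDs on a shared grid, renormalized."""
    if not uds:
        raise ValueError("need at least one UD")
    g = uds[0].grid
    if any(u.grid != g for u in uds[1:]):
        raise ValueError("UDs must share a grid")
    pmf = np.mean([u.pmf for u in uds], axis=0)
    return UDGrid(grid=g, pmf=pmf / pmf.sum())


def isopleth(ud: UDGrid, level: float) -> IsoplethMask:
    """Minimal set of highest-density cells holding at least ``level`` of
    the UD mass (50% = core foraging area, 95% = home range).  Ties are
    broken by stable flat cell index."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    flat = ud.pmf.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return IsoplethMask(
        level=level,
        mask=mask.reshape(ud.pmf.shape),
        contained_mass=float(csum[k - 1]),
    )


def bhattacharyya(a: UDGrid | np.ndarray, b: UDGrid | np.ndarray) -> float:
    """Bhattacharyya affinity sum_cells sqrt(pA * pB); 1 for identical
    distributions, 0 for disjoint supports."""
    pa = a.pmf if isinstance(a, UDGrid) else np.asarray(a, dtype=float)
    pb = b.pmf if isinstance(b, UDGrid) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("UDs must share a grid")
    return float(np.sum(np.sqrt(pa * pb)))


def _restrict(pmf: np.ndarray, level: float | None) -> np.ndarray:
    """Renormalize a UD within its own top-density isopleth."""
    if level is None:
        return pmf
    flat = pmf.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    out = np.zeros_like(flat)
    sel = order[:k]
    out[sel] = flat[sel] / flat[sel].sum()
    return out.reshape(pmf.shape)


def _group_ba(stack: np.ndarray, in_a: np.ndarray, level: float | None) -> float:
    pa = stack[in_a].mean(axis=0)
    pb = stack[~in_a].mean(axis=0)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.sum(np.sqrt(_restrict(pa, level) * _restrict(pb, level))))


def segregation_test(
    uds_a: list[UDGrid],
    uds_b: list[UDGrid],
    n_iter: int = 1000,
    seed: int | None = None,
    isopleth_level: float | None = None,
    plus_one: bool = False,
) -> OverlapResult:
    """Trip-randomization test of spatial segregation between two colonies.

    The observed statistic is the Bhattacharyya affinity between the two
    population UDs.  Trips (their precomputed UDs) are randomly reassigned
    to colonies, preserving group sizes, and the population UDs and BA are
    recomputed; the p-value is the proportion of randomizations whose BA is
    *smaller* than the observed one (strong segregation gives an observed
    BA below essentially the whole null sample, hence a small p).

    ``isopleth_level`` restricts the comparison to each population's own
    top-density isopleth (0.5 = core foraging areas, 0.95 = home ranges),
    renormalizing within the mask before computing BA.  ``plus_one`` uses
    the (r+1)/(n+1) permutation p-value instead of the plain proportion.
    """
    if len(uds_a) < 2 or len(uds_b) < 2:
        raise ValueError("need at least 2 trips per group")
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives an unstable p-value", stacklevel=2)
    g = uds_a[0].grid
    if any(u.grid != g for u in uds_a + uds_b):
        raise ValueError("all UDs must share a grid")
    stack = np.stack([u.pmf for u in uds_a + uds_b]).astype(np.float64)
    n_a = len(uds_a)
    n = stack.shape[0]
    labels = np.zeros(n, dtype=bool)
    labels[:n_a] = True
    observed = _group_ba(stack, labels, isopleth_level)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    if isopleth_level is None:
        # vectorized randomizations: group sums via BLAS on an indicator
        # matrix, chunked to bound memory; float32 is ample for a
        # permutation null
        flat = stack.reshape(n, -1).astype(np.float32)
        total = flat.sum(axis=0)
        n_cells = flat.shape[1]
        chunk = max(1, int(2e7 // n_cells))
        for start in range(0, n_iter, chunk):
            k = min(chunk, n_iter - start)
            ind = np.zeros((k, n), dtype=np.float32)
            for j in range(k):
                ind[j, rng.permutation(n)[:n_a]] = 1.0
            sum_a = ind @ flat
            sum_b = total[None, :] - sum_a
            pa = sum_a / sum_a.sum(axis=1, keepdims=True)
            pb = sum_b / sum_b.sum(axis=1, keepdims=True)
            null[start : start + k] = np.sqrt(pa * pb).sum(axis=1)
    else:
        for i in range(n_iter):
            perm = rng.permutation(n)
            in_a = np.zeros(n, dtype=bool)
            in_a[perm[:n_a]] = True
            null[i] = _group_ba(stack, in_a, isopleth_level)
    smaller = int(np.sum(null < observed))
    p = (smaller + 1) / (n_iter + 1) if plus_one else smaller / n_iter
    return OverlapResult(
        observed_ba=observed,
        null_ba=null,
        p_value=float(p),
        n_iter=n_iter,
        seed=seed,
        isopleth_level=isopleth_level,
    )


@dataclass(frozen=True)
class RepresentativenessResult:
    percent: float
    inclusion_by_size: dict[int, float]
    asymptote: float
    half_saturation: float
    low_confidence: bool


def representativeness(
    trip_xy: list[tuple[np.ndarray, np.ndarray]],
    bandwidth_km: float,
    grid: GridSpec,
    n_boot: int = 50,
    seed: int | None = None,
    level: float = 0.5,
) -> RepresentativenessResult:
    """Bootstrap assessment of how much of the population's core area the
    tracked sample captured.

    For each subsample size s = 1..N-1, random trip subsets are drawn and
    the mean fraction of out-of-sample fixes falling inside the subset's
    50% isopleth is recorded.  A saturating curve y = a*s/(b+s) is fitted
    to the inclusion-vs-size points, and the result is the fitted inclusion
    at the full sample size as a percentage of the asymptote a (capped at
    100).  Values near 100 mean additional tracked trips would add little
    new core area.
    """
    n = len(trip_xy)
    if n < 2:
        raise ValueError("need at least 2 trips")
    rng = np.random.default_rng(seed)
    uds = [kde_ud(x, y, bandwidth_km, grid).pmf for x, y in trip_xy]
    stack = np.stack(uds)
    # flat cell index per fix, per trip (fixes are inside the padded grid)
    flat_idx = []
    for x, y in trip_xy:
        ix, iy = grid.index_of(x, y)
        ix = np.clip(ix, 0, grid.nx - 1)
        iy = np.clip(iy, 0, grid.ny - 1)
        flat_idx.append(iy * grid.nx + ix)
    sizes = np.arange(1, n)
    inclusion = np.zeros(len(sizes))
    for si, s in enumerate(sizes):
        vals = np.empty(n_boot)
        for b in range(n_boot):
            subset = rng.choice(n, size=s, replace=False)
            pmf = stack[subset].mean(axis=0)
            pmf = pmf / pmf.sum()
            core = _restrict(pmf, level) > 0
            core_flat = core.ravel()
            out = np.setdiff1d(np.arange(n), subset)
            inside = np.concatenate([core_flat[flat_idx[i]] for i in out])
            vals[b] = inside.mean()
        inclusion[si] = vals.mean()
    incl_by_size = {int(s): float(v) for s, v in zip(sizes, inclusion)}
    if len(sizes) < 2:
        return RepresentativenessResult(
            percent=min(100.0, 100.0 * float(inclusion[0])),
            inclusion_by_size=incl_by_size,
            asymptote=float("nan"),
            half_saturation=float("nan"),
            low_confidence=True,
        )
    def hyperbola(s, a, b):
        return a * s / (b + s)
    try:
        (a_hat, b_hat), _ = optimize.curve_fit(
            hyperbola,
            sizes.astype(float),
            inclusion,
            p0=[max(inclusion.max(), 1e-3), 1.0],
            bounds=([1e-6, 1e-6], [1.0, 1e6]),
            maxfev=10000,
        )
    except RuntimeError:
        return RepresentativenessResult(
            percent=min(100.0, 100.0 * float(inclusion[-1])),
            inclusion_by_size=incl_by_size,
            asymptote=float("nan"),
            half_saturation=float("nan"),
            low_confidence=True,
        )
    percent = min(100.0, 100.0 * n / (b_hat + n))
    return RepresentativenessResult(
        percent=float(percent),
        inclusion_by_size=incl_by_size,
        asymptote=float(a_hat),
        half_saturation=float(b_hat),
        low_confidence=False,
    )


def individual_core_areas(
    bird_trip_xy: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    bandwidth_km: float,
    grid: GridSpec,
    level: float = 0.5,
) -> tuple[dict[str, IsoplethMask], np.ndarray]:
    """Per-bird core areas and the per-cell count of birds using each cell.

    Each bird's trips are pooled (mean of per-trip UDs) before taking the
    50% isopleth, so multi-trip birds are not over-weighted.
    """
    masks: dict[str, IsoplethMask] = {}
    counts = np.zeros((grid.ny, grid.nx), dtype=int)
    for bird, trips in bird_trip_xy.items():
        uds = [kde_ud(x, y, bandwidth_km, grid) for x, y in trips]
        ud = population_ud(uds)
        m = isopleth(ud, level)
        masks[bird] = m
        counts += m.mask.astype(int)
    return masks, counts
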