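"""High-level drivers tying the modules into the two-colony study analysis.

These functions are the programmatic equivalent of the CLI subcommands:
clean and segment tracks, build stage-wise utilization distributions on a
grid shared between colonies, run the segregation randomization test,
summarize wind at departure, and compute the fisheries-overlap table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pelagos import fisheries, tracks, ud, wind
from pelagos.geo import AzimuthalEquidistant
from pelagos.tracks import Colony, Trip


def clean_tracks(
    fixes: pd.DataFrame, vmax_kmh: float = 80.0, interval_h: float = 1.0
) -> pd.DataFrame:
    """Speed-filter then regularize to the common fix interval."""
    kept, _ = tracks.speed_filter(fixes, vmax_kmh=vmax_kmh)
    return tracks.regularize(kept, interval_h=interval_h)


def colony_trips(
    fixes: pd.DataFrame,
    colony: Colony,
    min_trip_h: float = 6.0,
    stage_windows=None,
) -> list[Trip]:
    """Trips of one colony's birds, with stages inferred."""
    sel = fixes[fixes["colony"] == colony.name]
    trips = tracks.split_trips(sel, colony, min_trip_h=min_trip_h)
    return tracks.infer_stage(trips, stage_windows)


@dataclass
class StageSegregation:
    stage: str
    projection: AzimuthalEquidistant
    grid: ud.GridSpec
    uds_a: list[ud.UDGrid]
    uds_b: list[ud.UDGrid]
    result: ud.OverlapResult


def project_trip_fixes(
    trips: list[Trip], projection: AzimuthalEquidistant
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for t in trips:
        x, y = projection.forward(t.fixes["lat"].to_numpy(), t.fixes["lon"].to_numpy())
        out.append((np.atleast_1d(x), np.atleast_1d(y)))
    return out


def stage_segregation(
    trips_a: list[Trip],
    trips_b: list[Trip],
    stage: str,
    colony_a: Colony,
    colony_b: Colony,
    spec: ud.SmoothingSpec | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    isopleth_level: float | None = None,
    complete_only: bool = True,
) -> StageSegregation:
    """Segregation test for one breeding stage.

    Per-trip UDs are estimated on a single grid covering both colonies'
    fixes (padded by three bandwidths), in an azimuthal-equidistant plane
    centred between the colonies, then randomized between colonies.
    """
    spec = spec or ud.SmoothingSpec()
    sel_a = [t for t in trips_a if t.stage == stage and (t.complete or not complete_only)]
    sel_b = [t for t in trips_b if t.stage == stage and (t.complete or not complete_only)]
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError(f"need at least 2 complete trips per colony in stage {stage}")
    center_lat = 0.5 * (colony_a.lat + colony_b.lat)
    center_lon = 0.5 * (colony_a.lon + colony_b.lon)
    proj = AzimuthalEquidistant(center_lat, center_lon)
    xy_a = project_trip_fixes(sel_a, proj)
    xy_b = project_trip_fixes(sel_b, proj)
    bw = spec.for_stage(stage)
    all_x = np.concatenate([x for x, _ in xy_a + xy_b])
    all_y = np.concatenate([y for _, y in xy_a + xy_b])
    grid = ud.make_grid(all_x, all_y, bw, spec.cell_km)
    uds_a = [ud.kde_ud(x, y, bw, grid) for x, y in xy_a]
    uds_b = [ud.kde_ud(x, y, bw, grid) for x, y in xy_b]
    result = ud.segregation_test(
        uds_a, uds_b, n_iter=n_iter, seed=seed, isopleth_level=isopleth_level
    )
    return StageSegregation(
        stage=stage, projection=proj, grid=grid, uds_a=uds_a, uds_b=uds_b, result=result
    )


def wind_summary_table(
    wind_table: pd.DataFrame, departures: pd.DataFrame
) -> pd.DataFrame:
    """Per colony-stage circular summaries of wind-at-departure direction."""
    speed, from_dir = wind.uv_to_wind(
        wind_table["u_ms"].to_numpy(), wind_table["v_ms"].to_numpy()
    )
    merged = wind_table.assign(speed_ms=speed, from_deg=from_dir).merge(
        departures[["trip_id", "colony", "stage"]], on="trip_id"
    )
    rows = []
    for (colony, stage), grp in merged.groupby(["colony", "stage"]):
        s = wind.circular_mean_sd(grp["from_deg"].to_numpy())
        rows.append(
            {
                "colony": colony,
                "stage": stage,
                "mean_from_deg": s.mean_deg,
                "sd_deg": s.sd_deg,
                "resultant_length": s.resultant_length,
                "mean_speed_ms": float(grp["speed_ms"].mean()),
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def overlap_table(
    fixes: pd.DataFrame,
    effort: pd.DataFrame,
    colonies: list[Colony],
    stage_windows=None,
) -> pd.DataFrame:
    """Per-stage, per-gear, per-flag overlap table for all colonies.

    ``fixes`` must already be regularized to the common interval so that
    fix counts are proportional to time.
    """
    windows = tracks._window_bounds(stage_windows or tracks.DEFAULT_STAGE_WINDOWS)
    shares = {}
    for colony in colonies:
        sel = fixes[fixes["colony"] == colony.name]
        for stage, (a, b) in windows.items():
            shares[(colony.name, stage)] = fisheries.time_share(sel, (a, b))
    return fisheries.overlap_by_group(shares, effort)
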