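"""Bird-by-fishery overlap on a 1-degree grid.

The overlap index for a colony and breeding stage is

    index = sum over cells of (proportion of tracked time in cell
                               x hours fished in cell),

a relative exposure measure, not a bycatch rate.  Time in a cell is the
count of regularized hourly fixes from all birds of the colony (the colony,
not the bird, is the normalization unit, so birds with more fixes weight
the share grid accordingly).  Because the breeding-stage date windows
differ in length and overlap in the calendar, index values are comparable
between colonies but not between stages; this caveat travels with every
output table as metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GEAR_TYPES = (
    "drifting_longline",
    "set_longline",
    "trawler",
    "squid_jigger",
    "pole_and_line",
    "unknown",
)

STAGE_CAVEAT = (
    "Stage windows differ in duration and overlap; index values can be "
    "compared among sites but not among breeding stages."
)


def cell_index(lat, lon) -> tuple[np.ndarray, np.ndarray]:
    """Half-open 1-degree binning: a position in [k, k+1) maps to index k;
    boundary fixes go to the lower(-left) cell."""
    lat_idx = np.floor(np.asarray(lat, dtype=float)).astype(int)
    lon_idx = np.floor(np.asarray(lon, dtype=float)).astype(int)
    return lat_idx, lon_idx


def validate_effort(effort: pd.DataFrame) -> pd.DataFrame:
    """Check an effort table (lat_idx, lon_idx, flag, gear, stage, hours)."""
    required = {"lat_idx", "lon_idx", "flag", "gear", "stage", "hours"}
    missing = required - set(effort.columns)
    if missing:
        raise ValueError(f"effort table missing columns: {sorted(missing)}")
    if (effort["hours"] < 0).any():
        raise ValueError("negative hours fished")
    bad = set(effort["gear"].unique()) - set(GEAR_TYPES)
    if bad:
        raise ValueError(f"unknown gear types: {sorted(bad)}")
    return effort


def time_share(
    fixes: pd.DataFrame, window: tuple[pd.Timestamp, pd.Timestamp] | None = None
) -> pd.DataFrame:
    """Proportion of a colony's (regularized, hourly) fix time per 1-degree
    cell within ``window`` (half-open).  Returns columns lat_idx, lon_idx,
    share, summing to 1."""
    f = fixes
    if window is not None:
        a, b = window
        f = f[(f["timestamp"] >= a) & (f["timestamp"] < b)]
    if len(f) == 0:
        warnings.warn("no fixes in window; empty share grid", stacklevel=2)
        return pd.DataFrame(columns=["lat_idx", "lon_idx", "share"])
    lat_idx, lon_idx = cell_index(f["lat"].to_numpy(), f["lon"].to_numpy())
    counts = (
        pd.DataFrame({"lat_idx": lat_idx, "lon_idx": lon_idx})
        .groupby(["lat_idx", "lon_idx"])
        .size()
        .rename("share")
        .reset_index()
    )
    counts["share"] = counts["share"] / counts["share"].sum()
    return counts


def overlap_index(
    shares: pd.DataFrame, effort: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Scalar overlap index and the per-cell contribution map.

    ``effort`` rows are summed per cell first, so a disaggregated table
    (multiple flags/gears per cell) gives the total-fishing index.
    """
    if len(shares) == 0 or len(effort) == 0:
        return 0.0, pd.DataFrame(columns=["lat_idx", "lon_idx", "contribution"])
    hours = effort.groupby(["lat_idx", "lon_idx"])["hours"].sum().reset_index()
    merged = shares.merge(hours, on=["lat_idx", "lon_idx"], how="inner")
    merged["contribution"] = merged["share"] * merged["hours"]
    return float(merged["contribution"].sum()), merged[
        ["lat_idx", "lon_idx", "contribution"]
    ]


def overlap_by_group(
    shares_by_colony_stage: dict[tuple[str, str], pd.DataFrame],
    effort: pd.DataFrame,
) -> pd.DataFrame:
    """Overlap index disaggregated by gear and flag state.

    ``shares_by_colony_stage`` maps (colony, stage) to a time-share grid;
    effort rows are matched on their own ``stage`` column.  The result has
    one row per (colony, stage, gear, flag) plus 'all' aggregates and a
    per-colony 'total' stage row; 'all' rows reconcile exactly with the sum
    of the disaggregated rows.  The table's ``attrs['caveat']`` carries the
    stage-comparability warning.
    """
    validate_effort(effort)
    rows = []
    for (colony, stage), shares in shares_by_colony_stage.items():
        eff_stage = effort[effort["stage"] == stage]
        idx_all, _ = overlap_index(shares, eff_stage)
        rows.append((colony, stage, "all", "all", idx_all))
        for gear, eff_gear in eff_stage.groupby("gear"):
            idx_g, _ = overlap_index(shares, eff_gear)
            rows.append((colony, stage, gear, "all", idx_g))
            for flag, eff_fg in eff_gear.groupby("flag"):
                idx_fg, _ = overlap_index(shares, eff_fg)
                rows.append((colony, stage, gear, flag, idx_fg))
    table = pd.DataFrame(rows, columns=["colony", "stage", "gear", "flag", "index"])
    totals = (
        table[(table["gear"] == "all") & (table["flag"] == "all")]
        .groupby("colony")["index"]
        .sum()
        .reset_index()
    )
    totals["stage"] = "total"
    totals["gear"] = "all"
    totals["flag"] = "all"
    table = pd.concat(
        [table, totals[["colony", "stage", "gear", "flag", "index"]]],
        ignore_index=True,
    )
    table.attrs["caveat"] = STAGE_CAVEAT
    return table
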