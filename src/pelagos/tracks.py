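"""Cleaning and segmentation of raw tracking fixes into colony-anchored
foraging trips, with breeding-stage inference and per-trip summary metrics.

Fixes live in a pandas DataFrame with columns ``bird_id``, ``colony``,
``timestamp`` (tz-aware UTC), ``lat``, ``lon``; timestamps are strictly
increasing within a bird.  A *trip* is the excursion between the last fix
inside the colony buffer before leaving and the first fix back inside it
(or the end of the record, in which case the trip is incomplete).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pelagos.geo import great_circle_km, initial_bearing

FIX_COLUMNS = ["bird_id", "colony", "timestamp", "lat", "lon"]

STAGES = ("incubation", "brood_guard", "postguard")

#: Breeding-stage calendar windows, half-open [start, end) at UTC midnight;
#: the end boundary is the midnight after the last day of the stage, so the
#: printed last day belongs to the window.  Incubation and brood guard
#: overlap in March, brood guard and postguard in April; the overlap zones
#: are resolved by colony attendance (see infer_stage).
DEFAULT_STAGE_WINDOWS: dict[str, tuple[str, str]] = {
    "incubation": ("2022-01-09", "2022-03-30"),
    "brood_guard": ("2022-03-02", "2022-04-19"),
    "postguard": ("2022-04-05", "2022-08-19"),
}


@dataclass(frozen=True)
class Colony:
    """A breeding colony: the central place trips start from and return to.

    ``buffer_km`` is the radius within which a bird counts as "at the
    colony" for trip splitting and attendance.
    """

    name: str
    lat: float
    lon: float
    buffer_km: float = 5.0

    def __post_init__(self):
        if not (np.isfinite(self.lat) and np.isfinite(self.lon)):
            raise ValueError("non-finite colony coordinates")
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be positive")


@dataclass
class Trip:
    """One foraging trip: ordered fixes anchored at the colony."""

    trip_id: str
    bird_id: str
    colony: str
    fixes: pd.DataFrame
    complete: bool
    stage: str | None = None
    #: hours the bird stayed inside the colony buffer after returning, NaN
    #: if the record ends before the bird leaves again
    attendance_after_h: float = field(default=np.nan)

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]


@dataclass(frozen=True)
class TripMetrics:
    duration_h: float
    total_distance_km: float
    foraging_range_km: float
    bearing_far_deg: float


def _check_fixes(fixes: pd.DataFrame) -> None:
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table missing columns: {missing}")


def speed_filter(
    fixes: pd.DataFrame, vmax_kmh: float = 80.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fixes implying unrealistic travel speeds.

    Sequential root-removal per bird: walking forward through the track,
    a fix is dropped when the speed from the previous *kept* fix exceeds
    ``vmax_kmh``.  This removes a single displaced outlier by itself,
    whereas pairwise deletion would also discard its innocent neighbour.

    Returns ``(kept, removed)`` DataFrames preserving the input row order.
    """
    _check_fixes(fixes)
    keep_mask = np.zeros(len(fixes), dtype=bool)
    for bird_id, grp in fixes.groupby("bird_id", sort=False):
        t = grp["timestamp"]
        if t.duplicated().any():
            raise ValueError(f"duplicate timestamps for bird {bird_id!r}")
        if not t.is_monotonic_increasing:
            raise ValueError(f"timestamps not increasing for bird {bird_id!r}")
        idx = grp.index.to_numpy()
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        hours = t.astype("int64").to_numpy() / 3.6e12
        last = 0
        keep_mask[fixes.index.get_loc(idx[0])] = True
        for i in range(1, len(idx)):
            d = great_circle_km(lat[last], lon[last], lat[i], lon[i])
            dt = hours[i] - hours[last]
            if d / dt <= vmax_kmh:
                keep_mask[fixes.index.get_loc(idx[i])] = True
                last = i
    return fixes[keep_mask], fixes[~keep_mask]


def _interp_segment(lat1, lon1, lat2, lon2, w):
    """Linear interpolation on the local plane between consecutive fixes,
    taking the short way round in longitude."""
    dlon = (lon2 - lon1 + 180.0) % 360.0 - 180.0
    lat = lat1 + w * (lat2 - lat1)
    lon = (lon1 + w * dlon + 180.0) % 360.0 - 180.0
    return lat, lon


def regularize(
    fixes: pd.DataFrame, interval_h: float = 1.0, max_gap_h: float = 12.0
) -> pd.DataFrame:
    """Resample each bird's track to exact clock-hour marks.

    Positions are linearly interpolated between the bracketing raw fixes;
    marks falling inside a raw-data gap longer than ``max_gap_h`` are left
    out rather than bridged.  Output timestamps are the multiples of
    ``interval_h`` (from UTC midnight) between each bird's first and last
    fix.
    """
    _check_fixes(fixes)
    step = pd.Timedelta(hours=interval_h)
    out = []
    for bird_id, grp in fixes.groupby("bird_id", sort=False):
        t = grp["timestamp"].reset_index(drop=True)
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        colony = grp["colony"].iloc[0]
        t0 = t.iloc[0].ceil(step)
        t1 = t.iloc[-1].floor(step)
        if t1 < t0:
            continue
        marks = pd.date_range(t0, t1, freq=step)
        tn = t.astype("int64").to_numpy()
        mn = marks.astype("int64").to_numpy()
        right = np.searchsorted(tn, mn, side="left")
        lats, lons, keep = [], [], []
        for k, (m, j) in enumerate(zip(mn, right)):
            if j < len(tn) and tn[j] == m:
                lats.append(lat[j])
                lons.append(lon[j])
                keep.append(k)
                continue
            i, jj = j - 1, j
            if i < 0 or jj >= len(tn):
                continue
            gap_h = (tn[jj] - tn[i]) / 3.6e12
            if gap_h > max_gap_h:
                continue
            w = (m - tn[i]) / (tn[jj] - tn[i])
            la, lo = _interp_segment(lat[i], lon[i], lat[jj], lon[jj], w)
            lats.append(la)
            lons.append(lo)
            keep.append(k)
        if keep:
            out.append(
                pd.DataFrame(
                    {
                        "bird_id": bird_id,
                        "colony": colony,
                        "timestamp": marks[keep],
                        "lat": lats,
                        "lon": lons,
                    }
                )
            )
    if not out:
        return fixes.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def split_trips(
    fixes: pd.DataFrame, colony: Colony, min_trip_h: float = 6.0
) -> list[Trip]:
    """Segment each bird's track into colony-anchored trips.

    A trip runs from the last fix inside the colony buffer before an
    excursion to the first fix back inside; excursions shorter than
    ``min_trip_h`` (near-colony loafing) or that never leave the buffer are
    dropped.  A terminal excursion with no return is emitted with
    ``complete=False``.
    """
    _check_fixes(fixes)
    trips: list[Trip] = []
    any_inside = False
    for bird_id, grp in fixes.groupby("bird_id", sort=False):
        grp = grp.reset_index(drop=True)
        dist = great_circle_km(
            colony.lat, colony.lon, grp["lat"].to_numpy(), grp["lon"].to_numpy()
        )
        inside = np.atleast_1d(dist) <= colony.buffer_km
        if inside.any():
            any_inside = True
        tn = grp["timestamp"].astype("int64").to_numpy() / 3.6e12
        n = len(grp)
        counter = 0
        i = 0
        # candidate trips bounded by inside->outside transitions
        bounds: list[tuple[int, int, bool]] = []  # (start idx, end idx incl., complete)
        while i < n:
            if not inside[i]:
                i += 1
                continue
            # find where the bird next leaves the buffer
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            if j + 1 >= n:
                break
            # excursion starts: last inside fix is j
            k = j + 1
            while k < n and not inside[k]:
                k += 1
            if k < n:
                bounds.append((j, k, True))
                i = k
            else:
                bounds.append((j, n - 1, False))
                break
        for b0, b1, complete in bounds:
            dur = tn[b1] - tn[b0]
            if dur < min_trip_h:
                continue
            counter += 1
            trip_fixes = grp.iloc[b0 : b1 + 1].reset_index(drop=True)
            trips.append(
                Trip(
                    trip_id=f"{bird_id}_t{counter:03d}",
                    bird_id=str(bird_id),
                    colony=colony.name,
                    fixes=trip_fixes,
                    complete=complete,
                )
            )
        # attendance after each complete trip = gap to next departure
        bird_trips = [t for t in trips if t.bird_id == str(bird_id)]
        for a, b in zip(bird_trips[:-1], bird_trips[1:]):
            a.attendance_after_h = (b.start - a.end).total_seconds() / 3600.0
    if not any_inside and len(fixes):
        warnings.warn("no fixes inside colony buffer; zero trips", stacklevel=2)
    return trips


def _window_bounds(stage_windows) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
    out = {}
    for stage, (a, b) in stage_windows.items():
        out[stage] = (pd.Timestamp(a, tz="UTC"), pd.Timestamp(b, tz="UTC"))
    return out


def infer_stage(
    trips: list[Trip],
    stage_windows: dict[str, tuple[str, str]] | None = None,
) -> list[Trip]:
    """Assign a breeding stage to each trip from the calendar and attendance.

    Stages are assigned by overlap of the trip with the stage windows.  In
    the zones where two windows overlap, a trip followed by more than 12 h
    of colony attendance goes to the earlier stage (incubation/brood-guard
    trips end in a long nest shift), otherwise to the later.  Trips whose
    post-trip attendance is unknown (end of record) fall back to the window
    covering the larger share of the trip.  Stages are set in place and the
    list is returned.
    """
    windows = _window_bounds(stage_windows or DEFAULT_STAGE_WINDOWS)
    order = [s for s in STAGES if s in windows] + [
        s for s in windows if s not in STAGES
    ]
    for trip in trips:
        t0, t1 = trip.start, trip.end
        cands = []
        for stage in order:
            a, b = windows[stage]
            ov = (min(t1, b) - max(t0, a)).total_seconds()
            if ov > 0:
                cands.append((stage, ov))
        if not cands:
            trip.stage = None
            continue
        if len(cands) == 1:
            trip.stage = cands[0][0]
            continue
        att = trip.attendance_after_h
        if np.isfinite(att):
            trip.stage = cands[0][0] if att > 12.0 else cands[-1][0]
        else:
            trip.stage = max(cands, key=lambda c: c[1])[0]
    return trips


def trip_metrics(trip: Trip, colony: Colony) -> TripMetrics:
    """Duration, path length, foraging range and bearing to the farthest
    point of one trip."""
    f = trip.fixes
    if len(f) < 2:
        raise ValueError("trip must have at least 2 fixes")
    lat = f["lat"].to_numpy()
    lon = f["lon"].to_numpy()
    duration = (trip.end - trip.start).total_seconds() / 3600.0
    legs = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    total = float(np.sum(legs))
    dcol = np.atleast_1d(great_circle_km(colony.lat, colony.lon, lat, lon))
    imax = int(np.argmax(dcol))
    bearing = initial_bearing(colony.lat, colony.lon, lat[imax], lon[imax])
    return TripMetrics(
        duration_h=float(duration),
        total_distance_km=total,
        foraging_range_km=float(dcol[imax]),
        bearing_far_deg=float(bearing),
    )


def summarize_trips(
    trips: list[Trip], colony: Colony, include_incomplete: bool = False
) -> pd.DataFrame:
    """Tidy per-trip metric table.

    Incomplete trips are excluded by default: a trip cut short by the end of
    the record under-reports duration, distance and range and would bias
    summaries.
    """
    rows = []
    for t in trips:
        if not include_incomplete and not t.complete:
            continue
        m = trip_metrics(t, colony)
        rows.append(
            {
                "trip_id": t.trip_id,
                "bird_id": t.bird_id,
                "colony": t.colony,
                "stage": t.stage,
                "complete": t.complete,
                "duration_h": m.duration_h,
                "total_distance_km": m.total_distance_km,
                "foraging_range_km": m.foraging_range_km,
                "bearing_far_deg": m.bearing_far_deg,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trip_id",
            "bird_id",
            "colony",
            "stage",
            "complete",
            "duration_h",
            "total_distance_km",
            "foraging_range_km",
            "bearing_far_deg",
        ],
    )
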