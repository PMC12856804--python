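"""Readers/writers for the pipeline's plain-text interchange formats.

Tracks:      CSV ``bird_id,colony,timestamp_iso8601_utc,lat,lon``
Wind:        CSV ``trip_id,timestamp,u_ms,v_ms``
Effort:      CSV ``lat_center,lon_center,flag,gear,stage,hours`` (1-degree cells)
Covariates:  CSV long format ``lat,lon,name,value``
Isopleths:   GeoJSON polygons in WGS84 lon/lat.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from pelagos.geo import AzimuthalEquidistant
from pelagos.ud import IsoplethMask, UDGrid


def write_tracks(fixes: pd.DataFrame, path) -> None:
    out = fixes.rename(columns={"timestamp": "timestamp_iso8601_utc"}).copy()
    out["timestamp_iso8601_utc"] = pd.to_datetime(
        out["timestamp_iso8601_utc"], utc=True
    ).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp_iso8601_utc"], utc=True)
    return df[["bird_id", "colony", "timestamp", "lat", "lon"]]


def write_wind(wind: pd.DataFrame, path) -> None:
    out = wind.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_wind(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_effort(effort: pd.DataFrame, path) -> None:
    """Internal integer cell indices are written as cell-centre coordinates."""
    out = effort.copy()
    out["lat_center"] = out.pop("lat_idx") + 0.5
    out["lon_center"] = out.pop("lon_idx") + 0.5
    out[["lat_center", "lon_center", "flag", "gear", "stage", "hours"]].to_csv(
        path, index=False
    )


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["lat_idx"] = np.floor(df.pop("lat_center")).astype(int)
    df["lon_idx"] = np.floor(df.pop("lon_center")).astype(int)
    return df[["lat_idx", "lon_idx", "flag", "gear", "stage", "hours"]]


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov[["lat", "lon", "name", "value"]].to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ud_cells_to_frame(ud: UDGrid) -> pd.DataFrame:
    """Long table of non-empty cells: planar centre coordinates and mass."""
    xc, yc = ud.grid.centers()
    iy, ix = np.nonzero(ud.pmf > 0)
    return pd.DataFrame(
        {"x_km": xc[ix], "y_km": yc[iy], "mass": ud.pmf[iy, ix]}
    )


def isopleth_to_geojson(
    ud: UDGrid, masks: list[IsoplethMask], projection: AzimuthalEquidistant
) -> dict:
    """GeoJSON FeatureCollection of isopleth outlines in WGS84 lon/lat.

    Cell rectangles are merged on the planar grid and each ring vertex is
    unprojected; with 10-km cells the ring is dense enough that straight
    planar edges are a faithful rendering.
    """
    features = []
    c = ud.grid.cell_km
    for m in masks:
        iy, ix = np.nonzero(m.mask)
        cells = [
            box(
                ud.grid.x0 + i * c,
                ud.grid.y0 + j * c,
                ud.grid.x0 + (i + 1) * c,
                ud.grid.y0 + (j + 1) * c,
            )
            for i, j in zip(ix, iy)
        ]
        merged = unary_union(cells)
        geom = mapping(merged)

        def unproject(coords):
            out = []
            for ring_or_pt in coords:
                if isinstance(ring_or_pt[0], (list, tuple)):
                    out.append(unproject(ring_or_pt))
                else:
                    x, y = ring_or_pt[0], ring_or_pt[1]
                    lat, lon = projection.inverse(x, y)
                    out.append([float(lon), float(lat)])
            return out

        geom = {"type": geom["type"], "coordinates": unproject(geom["coordinates"])}
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "level": m.level,
                    "contained_mass": m.contained_mass,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)
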