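"""Quadrat data model, readers/writers, QC filtering and track geometry.

A survey is held as a pandas DataFrame with one row per 1 x 1 m photo
quadrat.  Required columns:

    quadrat_id, site_id, lon, lat, altitude_m, k, m, depth_m, reef,
    track_order

``k`` is the number of classification points (of ``m``, normally 25) labelled
as the focal taxon, so cover = k / m.  Optional projected planar coordinates
``x``, ``y`` (meters) are populated by :func:`project_coordinates`; every
distance computation in the package runs on them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kelpscape.errors import (
    ProjectionError,
    SchemaError,
    ValidationError,
)

REQUIRED_COLUMNS = (
    "quadrat_id",
    "site_id",
    "lon",
    "lat",
    "altitude_m",
    "k",
    "m",
    "depth_m",
    "reef",
    "track_order",
)

#: mean Earth radius, meters (IUGG)
EARTH_RADIUS_M = 6371008.8

#: QC window for camera altitude above the seabed; images closer than 0.4 m
#: or farther than 5 m are optically unreliable and excluded (boundaries kept).
DEFAULT_MIN_ALTITUDE = 0.4
DEFAULT_MAX_ALTITUDE = 5.0

#: consecutive along-track spacings above this are treated as track breaks
#: (diver surfacing / repositioning); transect sections may not span one.
DEFAULT_MAX_GAP = 10.0


def validate_quadrats(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and per-record invariants; return the frame with
    normalized dtypes.  Raises :class:`SchemaError` / :class:`ValidationError`.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = records.copy()
    for col in ("lon", "lat", "altitude_m", "depth_m"):
        out[col] = pd.to_numeric(out[col]).astype(float)
    for col in ("k", "m", "track_order"):
        out[col] = pd.to_numeric(out[col]).astype(int)
    out["reef"] = out["reef"].astype(bool)

    bad = out.index[(out["k"] < 0) | (out["k"] > out["m"])]
    if len(bad):
        qid = out.loc[bad[0], "quadrat_id"]
        raise ValidationError(
            f"quadrat {qid!r}: k={out.loc[bad[0], 'k']} outside [0, m={out.loc[bad[0], 'm']}]"
        )
    if (out["m"] < 1).any():
        qid = out.loc[out.index[out["m"] < 1][0], "quadrat_id"]
        raise ValidationError(f"quadrat {qid!r}: m < 1")
    if (out["track_order"] < 0).any():
        raise ValidationError("track_order must be non-negative")
    dup = out.duplicated(subset=["site_id", "track_order"])
    if dup.any():
        sid = out.loc[dup.idxmax(), "site_id"]
        raise ValidationError(f"duplicate track_order within site {sid!r}")
    if not np.isfinite(out[["lon", "lat"]].to_numpy(float)).all():
        raise ValidationError("non-finite lon/lat")
    return out


def cover(records: pd.DataFrame) -> pd.Series:
    """Cover fraction k/m per quadrat."""
    return records["k"] / records["m"]


# -- readers / writers ------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"


def read_quadrats(path, fmt: str | None = None) -> pd.DataFrame:
    """Read quadrat records from CSV or GeoJSON, validated; row order kept."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "geojson":
        with path.open() as fh:
            fc = json.load(fh)
        rows = []
        for feat in fc.get("features", []):
            props = dict(feat.get("properties", {}))
            lon, lat = feat["geometry"]["coordinates"][:2]
            props["lon"], props["lat"] = lon, lat
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return validate_quadrats(df)


def write_quadrats(records: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write quadrat records as CSV or GeoJSON Point features."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        records.to_csv(path, index=False, float_format="%.9g")
    elif fmt == "geojson":
        feats = []
        for _, row in records.iterrows():
            props = {
                c: (bool(row[c]) if c == "reef" else row[c])
                for c in records.columns
                if c not in ("lon", "lat")
            }
            props = {k: (v.item() if hasattr(v, "item") else v) for k, v in props.items()}
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["lon"]), float(row["lat"])],
                    },
                    "properties": props,
                }
            )
        with path.open("w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# -- QC ---------------------------------------------------------------------


@dataclass
class AltitudeFilterReport:
    n_input: int
    n_kept: int
    n_excluded_low: int
    n_excluded_high: int
    min_alt: float
    max_alt: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def apply_altitude_filter(
    records: pd.DataFrame,
    min_alt: float = DEFAULT_MIN_ALTITUDE,
    max_alt: float = DEFAULT_MAX_ALTITUDE,
) -> tuple[pd.DataFrame, AltitudeFilterReport]:
    """Drop quadrats imaged too close or too far from the seabed.

    Exclusion is strict (altitude < min_alt or > max_alt); records exactly at
    a boundary are kept.  Returns the filtered frame and an exclusion report.
    """
    alt = pd.to_numeric(records["altitude_m"]) if len(records) else pd.Series(dtype=float)
    if (alt < 0).any():
        raise ValidationError("negative camera altitude")
    low = alt < min_alt
    high = alt > max_alt
    kept = records.loc[~(low | high)]
    report = AltitudeFilterReport(
        n_input=len(records),
        n_kept=len(kept),
        n_excluded_low=int(low.sum()),
        n_excluded_high=int(high.sum()),
        min_alt=min_alt,
        max_alt=max_alt,
    )
    return kept, report


# -- local projection -------------------------------------------------------


def project_coordinates(
    records: pd.DataFrame,
    origin: tuple[float, float] | None = None,
    max_extent_m: float = 20_000.0,
) -> pd.DataFrame:
    """Populate planar x, y (meters) via a local equirectangular projection.

    ``origin`` is (lon, lat) in degrees; default is the survey centroid.  At
    site scale (< ~20 km) the distance distortion of the equirectangular
    projection about a local origin is far below 0.1%.
    """
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    coslat0 = math.cos(math.radians(lat0))
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * coslat0
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    span = max(x.max() - x.min(), y.max() - y.min()) if len(records) else 0.0
    if span > max_extent_m:
        raise ProjectionError(
            f"extent {span/1000:.1f} km exceeds the validity of a single local "
            "projection; use per-site origins"
        )
    out = records.copy()
    out["x"] = x
    out["y"] = y
    return out


def unproject_coordinates(x, y, origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_coordinates` for the same origin."""
    lon0, lat0 = origin
    coslat0 = math.cos(math.radians(lat0))
    lon = lon0 + np.degrees(np.asarray(x, float) / (EARTH_RADIUS_M * coslat0))
    lat = lat0 + np.degrees(np.asarray(y, float) / EARTH_RADIUS_M)
    return lon, lat


# -- along-track geometry ---------------------------------------------------


@dataclass
class SurveyTrack:
    """One site's quadrats ordered along the dive track.

    ``cum_dist[i]`` is the cumulative planar distance from the first quadrat;
    ``gap_breaks`` holds indices i where the spacing from quadrat i-1 to i
    exceeds ``max_gap`` (a transect section may not span such a break).
    """

    site_id: str
    index: np.ndarray  # positional indices into the source frame
    x: np.ndarray
    y: np.ndarray
    cum_dist: np.ndarray
    gap_breaks: np.ndarray
    max_gap: float
    covers: np.ndarray = field(default=None)  # k/m per quadrat, track order

    @property
    def n(self) -> int:
        return len(self.cum_dist)

    @property
    def length(self) -> float:
        return float(self.cum_dist[-1])

    def segments(self) -> list[tuple[int, int]]:
        """Maximal gap-free runs as half-open positional ranges [a, b)."""
        bounds = [0, *self.gap_breaks.tolist(), self.n]
        return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def build_track(records: pd.DataFrame, max_gap: float = DEFAULT_MAX_GAP) -> SurveyTrack:
    """Order one site's quadrats by ``track_order`` and accumulate distance.

    Requires projected x, y.  Raises on duplicate track_order or fewer than
    two records.
    """
    if records["site_id"].nunique() > 1:
        raise ValidationError("build_track expects records from a single site")
    if len(records) < 2:
        raise ValidationError("need at least 2 quadrats to build a track")
    if "x" not in records.columns or "y" not in records.columns:
        raise ValidationError("records must be projected (missing x/y)")
    if records["track_order"].duplicated().any():
        raise ValidationError(
            f"duplicate track_order within site {records['site_id'].iloc[0]!r}"
        )
    ordered = records.sort_values("track_order")
    x = ordered["x"].to_numpy(float)
    y = ordered["y"].to_numpy(float)
    spacing = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(spacing)])
    breaks = np.flatnonzero(spacing > max_gap) + 1
    return SurveyTrack(
        site_id=str(ordered["site_id"].iloc[0]),
        index=ordered.index.to_numpy(),
        x=x,
        y=y,
        cum_dist=cum,
        gap_breaks=breaks,
        max_gap=max_gap,
        covers=(ordered["k"] / ordered["m"]).to_numpy(float),
    )
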