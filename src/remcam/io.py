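"""Readers and writers for the tabular and geometric inputs/outputs.

Tables are comma-separated UTF-8 CSV with a header row and ISO-8601
datetimes; a ``column_map`` translates foreign column names. Validation is
fail-fast with row-addressed messages; ``permissive=True`` logs and skips
bad rows instead. Polygons travel as GeoJSON FeatureCollections whose
coordinates are planar km (the package never does lon/lat math; a file that
declares a geographic CRS is rejected).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from datetime import datetime
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .types import (
    Deployment,
    DetectionTrial,
    EventRecord,
    FollowLog,
    HabitatMap,
    PrideRecord,
    REMParams,
    SchemaError,
    ValidationError,
    parse_angle,
    parse_length_km,
)

log = logging.getLogger("remcam.io")

_GEOGRAPHIC_CRS_HINTS = ("4326", "crs84", "wgs84", "longlat")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


def _read_csv(path, column_map: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_dt(value: str, where: str) -> datetime:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{where}: unparseable timestamp {value!r}") from exc
    if pd.isna(ts):
        raise ValidationError(f"{where}: missing timestamp")
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts.to_pydatetime()


def _collect(rows, permissive: bool, what: str):
    out, bad = [], []
    for rowno, build in rows:
        try:
            out.append(build())
        except ValidationError as exc:
            if permissive:
                log.warning("%s row %d skipped: %s", what, rowno, exc)
                bad.append(rowno)
            else:
                raise ValidationError(f"{what} row {rowno}: {exc}") from exc
    if bad:
        log.warning("%s: skipped %d invalid row(s)", what, len(bad))
    return out


def read_deployments(path, column_map=None, permissive: bool = False) -> List[Deployment]:
    """Read a camera deployment table (camera_id, x_km, y_km, start, end, habitat)."""
    df = _read_csv(path, column_map)
    _require_columns(df, ["camera_id", "x_km", "y_km", "start", "end"], "deployments")

    def build(rowno, row):
        def make():
            return Deployment(
                camera_id=str(row["camera_id"]),
                x=float(row["x_km"]),
                y=float(row["y_km"]),
                start=_parse_dt(row["start"], f"row {rowno}"),
                end=_parse_dt(row["end"], f"row {rowno}"),
                habitat=str(row.get("habitat", "") or ""),
            )
        return make

    deps = _collect(
        ((i + 2, build(i + 2, row)) for i, row in enumerate(df.to_dict("records"))),
        permissive, "deployments",
    )
    ids = [d.camera_id for d in deps]
    dupes = {c for c in ids if ids.count(c) > 1}
    if dupes:
        raise ValidationError(f"deployments: duplicate camera_id(s) {sorted(dupes)}")
    return deps


def write_deployments(deployments: Sequence[Deployment], path) -> None:
    pd.DataFrame(
        [
            {
                "camera_id": d.camera_id,
                "x_km": d.x,
                "y_km": d.y,
                "start": d.start.isoformat(),
                "end": d.end.isoformat(),
                "habitat": d.habitat,
            }
            for d in deployments
        ]
    ).to_csv(path, index=False)


def read_events(
    path,
    deployments: Optional[Sequence[Deployment]] = None,
    column_map=None,
    permissive: bool = False,
) -> List[EventRecord]:
    """Read a photographic event table, sorted by (camera_id, timestamp).

    When ``deployments`` is given, every event's camera_id must resolve to a
    deployment and its timestamp must fall within the active interval.
    """
    df = _read_csv(path, column_map)
    _require_columns(df, ["camera_id", "timestamp"], "events")
    by_id = {d.camera_id: d for d in deployments} if deployments is not None else None

    def build(rowno, row):
        def make():
            rec = EventRecord(
                camera_id=str(row["camera_id"]),
                timestamp=_parse_dt(row["timestamp"], f"row {rowno}"),
                species=str(row.get("species", "") or "lion"),
                sex=str(row.get("sex", "") or "female"),
                count=int(float(row.get("count", 1) or 1)),
            )
            if by_id is not None:
                dep = by_id.get(rec.camera_id)
                if dep is None:
                    raise ValidationError(f"unknown camera_id {rec.camera_id!r}")
                if not (dep.start <= rec.timestamp <= dep.end):
                    raise ValidationError(
                        f"timestamp {rec.timestamp} outside deployment interval of {rec.camera_id!r}"
                    )
            return rec
        return make

    events = _collect(
        ((i + 2, build(i + 2, row)) for i, row in enumerate(df.to_dict("records"))),
        permissive, "events",
    )
    return sorted(events, key=lambda e: (e.camera_id, e.timestamp))


def write_events(events: Sequence[EventRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "camera_id": e.camera_id,
                "timestamp": e.timestamp.isoformat(),
                "species": e.species,
                "sex": e.sex,
                "count": e.count,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def events_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Events as a DataFrame (camera_id, timestamp, species, sex, count)."""
    if isinstance(events, pd.DataFrame):
        return events
    return pd.DataFrame(
        {
            "camera_id": [e.camera_id for e in events],
            "timestamp": pd.to_datetime([e.timestamp for e in events]),
            "species": [e.species for e in events],
            "sex": [e.sex for e in events],
            "count": [e.count for e in events],
        }
    )


def read_habitat_map(path) -> HabitatMap:
    """Read habitat polygons from a GeoJSON FeatureCollection (planar km).

    Each feature needs a ``habitat`` property. Files declaring a geographic
    (lon/lat) CRS are rejected: the package works in projected km only.
    """
    with open(path) as fh:
        gj = json.load(fh)
    crs = gj.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", "")).lower()
        if any(h in name for h in _GEOGRAPHIC_CRS_HINTS):
            raise ValidationError(
                f"habitat map {path}: geographic CRS {name!r}; coordinates must be planar km"
            )
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"habitat map {path}: expected a FeatureCollection")
    polys = {}
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        label = props.get("habitat")
        if label is None:
            raise SchemaError(f"habitat map {path}: feature {i} has no 'habitat' property")
        if label in polys:
            raise ValidationError(f"habitat map {path}: duplicate habitat label {label!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValidationError(
                f"habitat map {path}: feature {i} ({label!r}) has invalid geometry"
            )
        polys[label] = geom
    return HabitatMap(polys)


def write_habitat_map(habitat_map: HabitatMap, path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"habitat": name}, "geometry": mapping(geom)}
            for name, geom in habitat_map.polygons.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_geojson(geometries: dict, path) -> None:
    """Write named geometries (hulls, buffers, isopleths) as GeoJSON."""
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
            for name, geom in geometries.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_trials(path, column_map=None) -> DetectionTrial:
    """Read detection-zone trial measurements.

    Schema: ``kind`` ('radius' or 'angle'); radius rows carry ``distance_m``;
    angle rows carry ``bearing_left_deg`` and ``bearing_right_deg``.
    """
    df = _read_csv(path, column_map)
    _require_columns(df, ["kind"], "trials")
    distances, pairs = [], []
    for i, row in enumerate(df.to_dict("records")):
        rowno = i + 2
        kind = str(row["kind"]).strip().lower()
        if kind == "radius":
            try:
                distances.append(float(row["distance_m"]))
            except (KeyError, TypeError, ValueError):
                raise ValidationError(f"trials row {rowno}: radius row needs distance_m")
        elif kind == "angle":
            try:
                pairs.append((float(row["bearing_left_deg"]) % 360.0,
                              float(row["bearing_right_deg"]) % 360.0))
            except (KeyError, TypeError, ValueError):
                raise ValidationError(
                    f"trials row {rowno}: angle row needs bearing_left_deg and bearing_right_deg"
                )
        else:
            raise ValidationError(f"trials row {rowno}: unknown kind {kind!r}")
    return DetectionTrial(radial_distances=tuple(distances), bearing_pairs=tuple(pairs))


def write_trials(trial: DetectionTrial, path) -> None:
    rows = [{"kind": "radius", "distance_m": d, "bearing_left_deg": "", "bearing_right_deg": ""}
            for d in trial.radial_distances]
    rows += [{"kind": "angle", "distance_m": "", "bearing_left_deg": lb, "bearing_right_deg": rb}
             for lb, rb in trial.bearing_pairs]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_follows(path, column_map=None) -> List[FollowLog]:
    """Read continuous-follow logs (pride_id, habitat, season, start, end, distance_km)."""
    df = _read_csv(path, column_map)
    _require_columns(df, ["pride_id", "start", "end", "distance_km"], "follows")
    follows = []
    for (pride, habitat, season), grp in df.groupby(
        [df["pride_id"], df.get("habitat", pd.Series("", index=df.index)).fillna(""),
         df.get("season", pd.Series("", index=df.index)).fillna("")],
        sort=True,
    ):
        segs = []
        for i, row in grp.iterrows():
            rowno = i + 2
            segs.append(
                (
                    _parse_dt(row["start"], f"follows row {rowno}"),
                    _parse_dt(row["end"], f"follows row {rowno}"),
                    float(row["distance_km"]),
                )
            )
        segs.sort(key=lambda s: s[0])
        follows.append(FollowLog(pride_id=str(pride), habitat=str(habitat),
                                 season=str(season), segments=tuple(segs)))
    return follows


def write_follows(follows: Sequence[FollowLog], path) -> None:
    rows = []
    for f in follows:
        for s, e, km in f.segments:
            rows.append(
                {
                    "pride_id": f.pride_id,
                    "habitat": f.habitat,
                    "season": f.season,
                    "start": s.isoformat(),
                    "end": e.isoformat(),
                    "distance_km": km,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prides(prides_path, observations_path, column_map=None) -> List[PrideRecord]:
    """Read a pride census table plus observation points.

    ``prides.csv``: pride_id, n_females, season. ``observations.csv``:
    pride_id, x_km, y_km, timestamp[, season].
    """
    pr = _read_csv(prides_path, column_map)
    _require_columns(pr, ["pride_id", "n_females"], "prides")
    ob = _read_csv(observations_path, column_map)
    _require_columns(ob, ["pride_id", "x_km", "y_km"], "pride observations")
    out = []
    for i, row in enumerate(pr.to_dict("records")):
        rowno = i + 2
        pid = str(row["pride_id"])
        season = str(row.get("season", "") or "")
        mask = ob["pride_id"].astype(str) == pid
        if "season" in ob.columns and season:
            mask &= ob["season"].fillna("").astype(str).isin(["", season])
        obs = []
        for j, orow in ob[mask].iterrows():
            ts = (
                _parse_dt(orow["timestamp"], f"observations row {j + 2}")
                if "timestamp" in ob.columns and not pd.isna(orow.get("timestamp"))
                else None
            )
            obs.append((float(orow["x_km"]), float(orow["y_km"]), ts))
        try:
            n_f = int(float(row["n_females"]))
        except (TypeError, ValueError):
            raise ValidationError(f"prides row {rowno}: bad n_females {row['n_females']!r}")
        out.append(PrideRecord(pride_id=pid, n_females=n_f, observations=tuple(obs), season=season))
    return out


def write_prides(prides: Sequence[PrideRecord], prides_path, observations_path) -> None:
    pd.DataFrame(
        [{"pride_id": p.pride_id, "n_females": p.n_females, "season": p.season} for p in prides]
    ).to_csv(prides_path, index=False)
    rows = []
    for p in prides:
        for x, y, ts in p.observations:
            rows.append(
                {
                    "pride_id": p.pride_id,
                    "x_km": x,
                    "y_km": y,
                    "timestamp": ts.isoformat() if ts is not None else "",
                    "season": p.season,
                }
            )
    pd.DataFrame(rows).to_csv(observations_path, index=False)


def load_params(path) -> REMParams:
    """Load REM parameters from YAML with explicit units.

    Expected keys: v_kmh, se_v_kmh, r with r_units ('m'|'km'), se_r, theta
    with theta_units ('deg'|'rad'), se_theta. Units are converted once here;
    everything downstream is km / radians.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        r_units = raw.get("r_units", "km")
        a_units = raw.get("theta_units", "rad")
        return REMParams(
            v=float(raw["v_kmh"]),
            se_v=float(raw.get("se_v_kmh", 0.0)),
            r=parse_length_km(float(raw["r"]), r_units),
            se_r=parse_length_km(float(raw.get("se_r", 0.0)), r_units),
            theta=parse_angle(float(raw["theta"]), a_units),
            se_theta=parse_angle(float(raw.get("se_theta", 0.0)), a_units),
        )
    except KeyError as exc:
        raise SchemaError(f"params file {path}: missing key {exc}") from exc


def dump_params(params: REMParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "v_kmh": params.v,
                "se_v_kmh": params.se_v,
                "r": params.r,
                "se_r": params.se_r,
                "r_units": "km",
                "theta": params.theta,
                "se_theta": params.se_theta,
                "theta_units": "rad",
            },
            fh,
        )


def write_results_json(results: dict, path) -> None:
    """Write a results dict as JSON, converting numpy scalars along the way."""

    def default(obj):
        if hasattr(obj, "item"):
            return obj.item()
        if isinstance(obj, datetime):
            return obj.isoformat()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, default=default)
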