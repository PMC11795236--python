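"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are UTF-8 CSV with a mandatory header row and
ISO-8601 dates/timestamps; polygons travel as GeoJSON FeatureCollections
(planar coordinates); the truth ledger as JSON. Schema validation is
strict: missing columns and unparseable values raise ``ValueError``
naming the file and the offending rows.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from coclimate.outage import OutageSeries
from coclimate.wildfire import DensityGrid, WildfireRecord

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_flags_csv",
    "write_flags_csv",
    "read_fires_csv",
    "write_fires_csv",
    "read_outage_series_csv",
    "write_outage_series_csv",
    "read_svi_csv",
    "write_svi_csv",
    "read_geometries_geojson",
    "write_geometries_geojson",
    "read_density_grid_geojson",
]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _parse_dates(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce")
    if parsed.isna().any():
        bad = df.index[parsed.isna()][:5].tolist()
        raise ValueError(f"{path}: unparseable {col} at rows {bad} (0-based)")
    return df.assign(**{col: parsed})


def read_temperature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["county", "date", "tmean_c"], path)
    df["county"] = df["county"].astype(str)
    return _parse_dates(df, "date", path)


def write_temperature_csv(df: pd.DataFrame, path) -> None:
    out = df[["county", "date", "tmean_c"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_flags_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["county", "date"], path)
    df["county"] = df["county"].astype(str)
    return _parse_dates(df, "date", path)


def write_flags_csv(flags: pd.DataFrame, path) -> None:
    cols = ["county", "date"] + (
        ["fire_id"] if "fire_id" in flags.columns else []
    )
    out = flags[cols].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


FIRE_COLUMNS = [
    "fire_id",
    "ignition_date",
    "containment_date",
    "structures_destroyed",
    "civilian_deaths",
    "fema_fmd",
    "community_overlap",
    "counties",
]


def write_fires_csv(fires: Iterable[WildfireRecord], path) -> None:
    """Fire table; the county list is semicolon-joined, empty when the
    footprint is a polygon (shipped separately as GeoJSON)."""
    rows = []
    for f in fires:
        rows.append(
            {
                "fire_id": f.fire_id,
                "ignition_date": f.ignition_date.isoformat(),
                "containment_date": f.containment_date.isoformat(),
                "structures_destroyed": f.structures_destroyed,
                "civilian_deaths": f.civilian_deaths,
                "fema_fmd": f.fema_fmd,
                "community_overlap": (
                    "" if f.community_overlap is None else f.community_overlap
                ),
                "counties": ";".join(f.counties) if f.counties else "",
            }
        )
    pd.DataFrame(rows, columns=FIRE_COLUMNS).to_csv(path, index=False)


def read_fires_csv(
    path, footprints: Mapping[str, BaseGeometry] | None = None
) -> list[WildfireRecord]:
    df = pd.read_csv(path, dtype={"counties": str, "community_overlap": str})
    _require_columns(df, FIRE_COLUMNS, path)
    df = _parse_dates(df, "ignition_date", path)
    df = _parse_dates(df, "containment_date", path)
    fires = []
    for i, row in df.iterrows():
        counties = row["counties"]
        county_list = (
            tuple(str(counties).split(";"))
            if isinstance(counties, str) and counties
            else None
        )
        footprint = None
        if county_list is None:
            if footprints is None or row["fire_id"] not in footprints:
                raise ValueError(
                    f"{path} row {i}: fire {row['fire_id']} has no county list "
                    "and no footprint geometry"
                )
            footprint = footprints[row["fire_id"]]
        comm = row["community_overlap"]
        if isinstance(comm, str) and comm.strip():
            community = comm.strip().lower() in ("true", "1", "yes")
        else:
            community = None
        fires.append(
            WildfireRecord(
                fire_id=str(row["fire_id"]),
                ignition_date=row["ignition_date"].date(),
                containment_date=row["containment_date"].date(),
                structures_destroyed=int(row["structures_destroyed"]),
                civilian_deaths=int(row["civilian_deaths"]),
                fema_fmd=bool(row["fema_fmd"]),
                counties=county_list,
                footprint=footprint,
                community_overlap=community,
            )
        )
    return fires


def write_outage_series_csv(
    series: Iterable[OutageSeries], series_path, meta_path
) -> None:
    recs, meta = [], []
    for s in series:
        rec = s.records.copy()
        rec.insert(0, "county", s.county)
        recs.append(rec)
        meta.append(
            {
                "county": s.county,
                "customers_total": s.customers_total,
                "reporting_fraction": s.reporting_fraction,
                "coverage_fraction": s.coverage_fraction,
            }
        )
    allrec = pd.concat(recs, ignore_index=True)
    allrec["timestamp"] = pd.to_datetime(allrec["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    allrec.to_csv(series_path, index=False)
    pd.DataFrame(meta).to_csv(meta_path, index=False)


def read_outage_series_csv(series_path, meta_path) -> list[OutageSeries]:
    rec = pd.read_csv(series_path)
    _require_columns(rec, ["county", "timestamp", "customers_out"], series_path)
    rec["county"] = rec["county"].astype(str)
    rec = _parse_dates(rec, "timestamp", series_path)
    meta = pd.read_csv(meta_path)
    _require_columns(
        meta,
        ["county", "customers_total", "reporting_fraction", "coverage_fraction"],
        meta_path,
    )
    meta["county"] = meta["county"].astype(str)
    series = []
    grouped = dict(list(rec.groupby("county")))
    for _, m in meta.iterrows():
        county = m["county"]
        sub = grouped.get(
            county, pd.DataFrame(columns=["timestamp", "customers_out"])
        )
        series.append(
            OutageSeries(
                county=county,
                records=sub[["timestamp", "customers_out"]].reset_index(drop=True),
                customers_total=int(m["customers_total"]),
                reporting_fraction=float(m["reporting_fraction"]),
                coverage_fraction=float(m["coverage_fraction"]),
            )
        )
    return series


def read_svi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["county", "svi"], path)
    df["county"] = df["county"].astype(str)
    return df[["county", "svi"]]


def write_svi_csv(df: pd.DataFrame, path) -> None:
    df[["county", "svi"]].to_csv(path, index=False)


def write_geometries_geojson(geoms: Mapping[str, BaseGeometry], path) -> None:
    """FeatureCollection with one feature per id (county or fire)."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"id": key},
                "geometry": mapping(geom),
            }
            for key, geom in geoms.items()
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geometries_geojson(path) -> dict[str, BaseGeometry]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = {}
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        key = props.get("id")
        if key is None:
            raise ValueError(f"{path}: feature {i} lacks an 'id' property")
        out[str(key)] = shape(feat["geometry"])
    return out


def read_density_grid_geojson(path) -> DensityGrid:
    """Cells with a ``density`` property in people/km^2."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    cells = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        if "density" not in props:
            raise ValueError(f"{path}: feature {i} lacks a 'density' property")
        cells.append((shape(feat["geometry"]), float(props["density"])))
    return DensityGrid(cells=tuple(cells))
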