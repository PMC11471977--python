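"""Readers and writers: occurrence CSV/TSV, taxon reference tables, GeoJSON regions.

Column names follow a Darwin-Core-style default mapping
(``scientificName``, ``decimalLatitude``, ``decimalLongitude``,
``coordinateUncertaintyInMeters``, ``year``) and can be remapped through
a config dict.  The delimiter is auto-detected among comma / tab /
semicolon.  Region geometries use RFC 7946 GeoJSON (lon-lat order,
WGS84).  Readers never silently drop rows: unparseable cells yield
absent values plus a flag.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

from .core import (
    Flag,
    GeometryError,
    LocalityPrecision,
    OccurrenceRecord,
    RegionPolygon,
    RegionSet,
    SchemaError,
    TaxonEntry,
    Taxonomy,
)
from .geography import dms_to_decimal
from .regionalization import polygon_area_km2

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_occurrences",
    "write_occurrences",
    "read_taxon_table",
    "write_taxon_table",
    "read_regions",
    "write_regions",
]

#: Default (field -> column header) mapping, Darwin-Core style.
DEFAULT_COLUMN_MAP = {
    "record_id": "occurrenceID",
    "source_id": "institutionCode",
    "raw_name": "scientificName",
    "accepted_name": "acceptedNameUsage",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "coordinate_uncertainty_m": "coordinateUncertaintyInMeters",
    "locality_precision": "localityPrecision",
    "year": "year",
}

_LIST_SEP = "|"


def _detect_delimiter(path: Path) -> str:
    sample = path.open("r", encoding="utf-8").readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in ("", "NA", "NaN", "nan")


def read_occurrences(
    path: Union[str, Path],
    column_map: Optional[dict] = None,
    delimiter: Optional[str] = None,
) -> list[OccurrenceRecord]:
    """Read an occurrence table into records, one per row.

    Coordinates may be decimal or DMS strings; unparseable coordinate
    cells yield absent coordinates plus ``COORD_PARSE_ERROR``, empty ones
    ``MISSING_COORD``.  Missing ``raw_name``/``source_id`` columns raise
    :class:`SchemaError` naming the column.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8", keep_default_na=False)
    for mandatory in ("raw_name", "source_id"):
        if cols[mandatory] not in df.columns:
            raise SchemaError(f"missing mandatory column {cols[mandatory]!r} in {path.name}")

    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        def cell(field_name):
            col = cols.get(field_name)
            if col is None or col not in df.columns:
                return None
            value = row[col]
            return None if _is_missing(value) else str(value).strip()

        flags: set = set()
        lat = lon = None
        lat_raw, lon_raw = cell("latitude"), cell("longitude")
        if lat_raw is None or lon_raw is None:
            flags.add(Flag.MISSING_COORD)
        else:
            try:
                lat = dms_to_decimal(lat_raw)
                lon = dms_to_decimal(lon_raw)
            except ValueError:
                lat = lon = None
                flags.add(Flag.COORD_PARSE_ERROR)
                flags.add(Flag.MISSING_COORD)

        unc_raw = cell("coordinate_uncertainty_m")
        unc = float(unc_raw) if unc_raw is not None else None
        year_raw = cell("year")
        year = None
        if year_raw is not None:
            try:
                year = int(float(year_raw))
            except ValueError:
                year = None
        prec_raw = cell("locality_precision")
        try:
            precision = LocalityPrecision(prec_raw) if prec_raw else LocalityPrecision.UNKNOWN
        except ValueError:
            precision = LocalityPrecision.UNKNOWN

        records.append(
            OccurrenceRecord(
                record_id=cell("record_id") or f"row{i}",
                source_id=cell("source_id"),
                raw_name=cell("raw_name") or "",
                accepted_name=cell("accepted_name"),
                latitude=lat,
                longitude=lon,
                coordinate_uncertainty_m=unc,
                locality_precision=precision,
                year=year,
                flags=flags,
            )
        )
    return records


def _format_float(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_occurrences(
    records: Iterable[OccurrenceRecord],
    path: Union[str, Path],
    column_map: Optional[dict] = None,
) -> None:
    """Write records as UTF-8 CSV with a deterministic column order."""
    cols = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cols.update(column_map)
    order = [
        "record_id", "source_id", "raw_name", "accepted_name",
        "latitude", "longitude", "coordinate_uncertainty_m",
        "locality_precision", "year",
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([cols[f] for f in order] + ["flags"])
        for rec in records:
            writer.writerow(
                [
                    rec.record_id,
                    rec.source_id or "",
                    rec.raw_name,
                    rec.accepted_name or "",
                    _format_float(rec.latitude),
                    _format_float(rec.longitude),
                    _format_float(rec.coordinate_uncertainty_m),
                    rec.locality_precision.value,
                    "" if rec.year is None else str(rec.year),
                    _LIST_SEP.join(sorted(f.value for f in rec.flags)),
                ]
            )


def read_taxon_table(path: Union[str, Path], delimiter: Optional[str] = None) -> Taxonomy:
    """Read the taxon reference table (accepted names, synonyms, codes, IUCN).

    Synonym lists are ``|``-separated; duplicate accepted rows merge by
    set union; the same synonym under two accepted names raises
    :class:`SchemaError` listing both.  An IUCN value of "NA" (not
    assessed) is stored as NE.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8", keep_default_na=False)
    required = ("accepted_name", "synonyms", "biome_codes", "iucn")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path.name}")
    taxonomy = Taxonomy(())
    for row in df.to_dict("records"):
        iucn = (row["iucn"] or "NE").strip().upper()
        if iucn in ("NA", ""):
            iucn = "NE"
        synonyms = {s.strip() for s in row["synonyms"].split(_LIST_SEP) if s.strip()}
        codes = {c.strip().upper() for c in row["biome_codes"].split(_LIST_SEP) if c.strip()}
        taxonomy.add(
            TaxonEntry(
                accepted_name=row["accepted_name"].strip(),
                order=(row.get("order") or "").strip(),
                family=(row.get("family") or "").strip(),
                synonyms=synonyms,
                biome_codes=codes,
                iucn_category=iucn,
            )
        )
    return taxonomy


def write_taxon_table(taxonomy: Taxonomy, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accepted_name", "order", "family", "synonyms", "biome_codes", "iucn"])
        for name in taxonomy.species():
            e = taxonomy.get(name)
            writer.writerow(
                [
                    e.accepted_name,
                    e.order,
                    e.family,
                    _LIST_SEP.join(sorted(e.synonyms)),
                    _LIST_SEP.join(sorted(e.biome_codes)),
                    e.iucn_category,
                ]
            )


def read_regions(path: Union[str, Path], repair: bool = True) -> RegionSet:
    """Read a GeoJSON FeatureCollection into a RegionSet.

    Invalid geometries are repaired with ``make_valid`` when ``repair``
    is on, otherwise rejected with :class:`GeometryError` naming the
    feature.  Missing ``level`` defaults to 0; ``area_km2`` is computed
    on the sphere when absent.
    """
    path = Path(path)
    collection = json.loads(path.read_text(encoding="utf-8"))
    if collection.get("type") != "FeatureCollection":
        raise GeometryError(f"{path.name}: not a GeoJSON FeatureCollection")
    regions = RegionSet()
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties") or {}
        fid = str(props.get("region_id", feature.get("id", f"feature{i}")))
        geom = shape(feature["geometry"])
        if not geom.is_valid:
            if not repair:
                raise GeometryError(f"invalid geometry for feature {fid}")
            geom = make_valid(geom)
        area = props.get("area_km2")
        regions.add(
            RegionPolygon(
                region_id=fid,
                name=str(props.get("name", fid)),
                level=int(props.get("level", 0)),
                parent_id=props.get("parent_id"),
                geometry=geom,
                area_km2=float(area) if area is not None else polygon_area_km2(geom),
            )
        )
    return regions


def write_regions(regions: RegionSet, path: Union[str, Path]) -> None:
    """Write a RegionSet as an RFC 7946 GeoJSON FeatureCollection."""
    features = []
    for r in regions:
        features.append(
            {
                "type": "Feature",
                "id": r.region_id,
                "properties": {
                    "region_id": r.region_id,
                    "name": r.name,
                    "level": r.level,
                    "parent_id": r.parent_id,
                    "area_km2": r.area_km2,
                },
                "geometry": mapping(r.geometry),
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True),
        encoding="utf-8",
    )
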