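"""Biogeographic validation (filter 3): biome containment and distribution vetting.

Records are kept when their point lies within the biome boundary (closed
boundary: points exactly on the edge count as inside) and their species
has the target biome among its documented distribution codes.  Species
with no mention of the target biome are dropped wholesale — every one of
their records is excluded — mirroring a review of dubious distributions
against reference platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .core import FilterReport, Flag, GeometryError, OccurrenceRecord, RegionPolygon, Taxonomy

__all__ = [
    "ContainmentResult",
    "point_in_polygon",
    "vet_species_distribution",
    "apply_biogeographic_filter",
]


@dataclass
class ContainmentResult:
    inside: bool
    region_id: Optional[str] = None


def point_in_polygon(lon: float, lat: float, polygon: BaseGeometry) -> bool:
    """Closed-boundary containment: edge and vertex points are inside.

    Holes are respected (a point inside a hole is outside).
    """
    if polygon.is_empty or not polygon.is_valid:
        raise GeometryError("invalid or empty polygon")
    return bool(polygon.covers(Point(lon, lat)))


def vet_species_distribution(
    species: str, taxonomy: Taxonomy, target_code: str = "AM"
) -> bool:
    """True (keep) iff the species' distribution codes mention the target biome.

    Species absent from the reference table are kept by default (flagged
    upstream) rather than silently dropped.
    """
    entry = taxonomy.get(species)
    if entry is None:
        return True
    return target_code in entry.biome_codes


def apply_biogeographic_filter(
    records: Iterable[OccurrenceRecord],
    biome: RegionPolygon,
    taxonomy: Taxonomy,
    target_code: str = "AM",
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]], FilterReport, list[str]]:
    """Filter 3: drop records outside the biome and records of non-target species.

    Returns (retained, excluded-with-reason, report slice, dropped
    species list).  Reasons distinguish ``outside_biome`` from
    ``non_target_distribution``.
    """
    records = list(records)
    dropped_species = sorted(
        {
            r.accepted_name
            for r in records
            if r.accepted_name
            and not vet_species_distribution(r.accepted_name, taxonomy, target_code)
        }
    )
    dropped_set = set(dropped_species)

    geom = biome.geometry if isinstance(biome, RegionPolygon) else biome
    if geom.is_empty or not geom.is_valid:
        raise GeometryError("invalid biome polygon")
    tree = STRtree([geom])

    retained: list[OccurrenceRecord] = []
    excluded: list[tuple[OccurrenceRecord, str]] = []
    for rec in records:
        name = rec.accepted_name or rec.raw_name
        if name in dropped_set:
            rec.flags.add(Flag.NON_TARGET_DISTRIBUTION)
            excluded.append((rec, "non_target_distribution"))
            continue
        inside = rec.has_coordinates and len(
            tree.query(Point(rec.longitude, rec.latitude), predicate="intersects")
        ) > 0
        if not inside:
            rec.flags.add(Flag.OUTSIDE_BIOME)
            excluded.append((rec, "outside_biome"))
            continue
        if rec.accepted_name and taxonomy.get(rec.accepted_name) is None:
            rec.flags.add(Flag.TAXON_NOT_IN_REFERENCE)
        retained.append(rec)

    report = FilterReport(len(records))
    n_species = len({r.accepted_name or r.raw_name for r in retained})
    report.record_stage("biogeographic", len(excluded), n_species)
    return retained, excluded, report, dropped_species
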