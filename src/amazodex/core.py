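"""Core domain types for occurrence curation and basin-level diversity analysis.

The pipeline operates on four kinds of objects: individual occurrence
records (one observation of a species at a place and time), a taxon
reference table (accepted names, synonyms, biome distribution codes, IUCN
categories), sets of region polygons (biome boundary, nested drainage
basins, grid cells), and the per-stage filter accounting report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from shapely.geometry.base import BaseGeometry

#: Biome / bioregion distribution codes used in the taxon reference table.
BIOME_CODES = frozenset(
    {"AM", "AF", "AN", "CA", "CE", "CH", "CB", "PA", "PM", "PN", "SPA", "NSA", "NW", "PC"}
)

#: IUCN Red List categories.  "NE" (not evaluated) also absorbs the
#: "NA / not assessed" label some sources print.
IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD", "NE")

#: Categories counted as threatened in conservation summaries.
THREATENED = frozenset({"CR", "EN", "VU"})


class LocalityPrecision(str, enum.Enum):
    """Described precision of a record's locality."""

    POINT = "point"
    LOCALITY = "locality"
    MUNICIPALITY = "municipality"
    STATE = "state"
    COUNTRY = "country"
    UNKNOWN = "unknown"


#: Precision levels that describe an administrative unit rather than a place.
ADMIN_PRECISIONS = frozenset(
    {LocalityPrecision.MUNICIPALITY, LocalityPrecision.STATE, LocalityPrecision.COUNTRY}
)


class Flag(str, enum.Enum):
    """Validation flags attached to records as they move through the filters."""

    MISSING_COORD = "missing_coord"
    COORD_PARSE_ERROR = "coord_parse_error"
    OPEN_NOMENCLATURE = "open_nomenclature"
    UNRESOLVED_NAME = "unresolved_name"
    SYNONYM_RESOLVED = "synonym_resolved"
    ZERO_ZERO = "zero_zero"
    OUT_OF_RANGE = "out_of_range"
    TOO_IMPRECISE = "too_imprecise"
    ADMIN_LEVEL = "admin_level"
    OUTSIDE_BIOME = "outside_biome"
    NON_TARGET_DISTRIBUTION = "non_target_distribution"
    TAXON_NOT_IN_REFERENCE = "taxon_not_in_reference"


class SchemaError(ValueError):
    """A required column is missing or a table violates its contract."""


class GeometryError(ValueError):
    """A geometry is invalid and repair is disabled."""


@dataclass
class OccurrenceRecord:
    """One species observation.

    Coordinates are decimal degrees on WGS84; ``coordinate_uncertainty_m``
    is the stated radius of uncertainty in metres.  ``flags`` accumulates
    validation outcomes; ``accepted_name`` is filled by the taxonomic
    filter once the verbatim name resolves.
    """

    record_id: str
    source_id: str
    raw_name: str
    accepted_name: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    coordinate_uncertainty_m: Optional[float] = None
    locality_precision: LocalityPrecision = LocalityPrecision.UNKNOWN
    year: Optional[int] = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            self.flags.add(Flag.OUT_OF_RANGE)
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            self.flags.add(Flag.OUT_OF_RANGE)
        if self.coordinate_uncertainty_m is not None and self.coordinate_uncertainty_m < 0:
            raise ValueError(
                f"record {self.record_id}: negative coordinate uncertainty"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class TaxonEntry:
    """Accepted binomial with synonyms, classification and distribution codes."""

    accepted_name: str
    order: str = ""
    family: str = ""
    genus: str = ""
    synonyms: set = field(default_factory=set)
    biome_codes: set = field(default_factory=set)
    iucn_category: str = "NE"

    def __post_init__(self) -> None:
        if self.accepted_name in self.synonyms:
            raise ValueError(
                f"{self.accepted_name}: accepted name listed among its own synonyms"
            )
        unknown = self.biome_codes - BIOME_CODES
        if unknown:
            raise ValueError(f"{self.accepted_name}: unknown biome codes {sorted(unknown)}")
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(f"{self.accepted_name}: unknown IUCN category {self.iucn_category}")
        if not self.genus:
            self.genus = self.accepted_name.split()[0]


class Taxonomy:
    """Taxon reference table: accepted names plus an injective synonym map."""

    def __init__(self, entries: Iterable[TaxonEntry]):
        self.entries: dict[str, TaxonEntry] = {}
        self.synonym_map: dict[str, str] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: TaxonEntry) -> None:
        existing = self.entries.get(entry.accepted_name)
        if existing is not None:
            # duplicate accepted rows merge by set union
            existing.synonyms |= entry.synonyms
            existing.biome_codes |= entry.biome_codes
            entry = existing
        else:
            self.entries[entry.accepted_name] = entry
        for syn in entry.synonyms:
            owner = self.synonym_map.get(syn)
            if owner is not None and owner != entry.accepted_name:
                raise SchemaError(
                    f"synonym {syn!r} listed under both {owner!r} and {entry.accepted_name!r}"
                )
            self.synonym_map[syn] = entry.accepted_name

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> Optional[TaxonEntry]:
        return self.entries.get(name)

    def species(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class RegionPolygon:
    """A polygon analysis unit: biome boundary, drainage basin, or grid cell."""

    region_id: str
    name: str = ""
    level: int = 0
    parent_id: Optional[str] = None
    geometry: Optional[BaseGeometry] = None
    area_km2: float = 0.0


class RegionSet:
    """Ordered collection of region polygons with id lookup and level access."""

    def __init__(self, regions: Iterable[RegionPolygon] = ()):
        self.regions: list[RegionPolygon] = list(regions)
        self._by_id = {r.region_id: r for r in self.regions}
        if len(self._by_id) != len(self.regions):
            raise ValueError("duplicate region ids")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, region_id: str) -> RegionPolygon:
        return self._by_id[region_id]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def add(self, region: RegionPolygon) -> None:
        if region.region_id in self._by_id:
            raise ValueError(f"duplicate region id {region.region_id}")
        self.regions.append(region)
        self._by_id[region.region_id] = region

    def at_level(self, level: int) -> list[RegionPolygon]:
        return [r for r in self.regions if r.level == level]

    def children_of(self, region_id: str) -> list[RegionPolygon]:
        return [r for r in self.regions if r.parent_id == region_id]

    def levels(self) -> list[int]:
        return sorted({r.level for r in self.regions})


class FilterReport:
    """Per-stage retained/excluded accounting.

    Maintains the conservation identity
    ``n_initial == n_retained + sum(stage exclusions)``; every record is
    counted in exactly one bucket.
    """

    def __init__(self, n_initial: int):
        self.n_initial = int(n_initial)
        self.excluded: dict[str, int] = {}
        self.retained_species: dict[str, int] = {}
        self.n_retained = int(n_initial)

    def record_stage(self, stage: str, n_excluded: int, n_species_retained: Optional[int] = None) -> None:
        if stage in self.excluded:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.excluded[stage] = int(n_excluded)
        self.n_retained -= int(n_excluded)
        if self.n_retained < 0:
            raise ValueError("exclusions exceed initial count")
        if n_species_retained is not None:
            self.retained_species[stage] = int(n_species_retained)

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    def check_identity(self) -> bool:
        return self.n_initial == self.n_retained + self.total_excluded
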