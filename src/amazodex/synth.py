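"""Synthetic occurrence data with known ground truth.

Emulates a multi-source occurrence compilation over a rectangular biome
with a three-level nested drainage hierarchy: records carry controlled
rates of open-nomenclature markers, synonym usage, missing or imprecise
coordinates, points outside the biome, and species with no documented
distribution in the target biome.  Every record's defects are recorded
in a :class:`TruthLedger` along with the FIRST filter stage that should
exclude it, so downstream filter counts can be checked exactly against
labels rather than rates.

Defects are applied independently per record in a fixed order (name,
then coordinates, then placement), mirroring sequential filtering: a
record may carry several defects but is charged to the earliest stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point, box

from .core import (
    BIOME_CODES,
    OccurrenceRecord,
    RegionPolygon,
    RegionSet,
    TaxonEntry,
    Taxonomy,
)
from .regionalization import polygon_area_km2

__all__ = ["GeneratorConfig", "TruthLedger", "generate_landscape", "generate_taxonomy",
           "generate_occurrences"]

_SOURCE_NAMES = ("gbif", "specieslink", "vertnet", "sibbr", "sisbio",
                 "articles", "grey_literature", "fieldwork")

_GENUS_STEMS = (
    "Rhinella", "Boana", "Pristimantis", "Osteocephalus", "Adenomera", "Scinax",
    "Allobates", "Leptodactylus", "Trachycephalus", "Ameerega", "Dendropsophus",
    "Phyllomedusa", "Atelopus", "Caecilia", "Bolitoglossa", "Synapturanus",
    "Chiasmocleis", "Ranitomeya", "Hypsiboas", "Vitreorana",
)

_FAMILIES = (
    ("Bufonidae", "Anura"), ("Hylidae", "Anura"), ("Strabomantidae", "Anura"),
    ("Leptodactylidae", "Anura"), ("Dendrobatidae", "Anura"),
    ("Microhylidae", "Anura"), ("Caeciliidae", "Gymnophiona"),
    ("Plethodontidae", "Caudata"),
)

_SYLLABLES = ("ama", "zo", "ni", "cus", "ra", "ve", "lu", "ta", "mi", "dor",
              "pe", "sil", "va", "ge", "o", "fla", "vi", "ri", "ma", "cu")

#: IUCN category draw probabilities, roughly matching a large tropical
#: amphibian assemblage (mostly LC, ~20 % threatened, some DD/NE).
_IUCN_PROBS = {"LC": 0.62, "EN": 0.11, "VU": 0.059, "CR": 0.051,
               "NT": 0.046, "DD": 0.072, "NE": 0.042}

_MARKER_FORMS = ("cf.", "aff.", "gr.", "sp.")


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic dataset.  All rates are per-record probabilities."""

    seed: Optional[int] = None
    n_species: int = 60
    n_sources: int = 5
    records_per_source: Optional[list[int]] = None  # default scales to ~5000
    open_nomenclature_rate: float = 0.24
    synonym_use_rate: float = 0.15
    missing_coord_rate: float = 0.45
    imprecise_coord_rate: float = 0.07
    outside_biome_rate: float = 0.25
    dubious_species_fraction: float = 0.09
    endemic_fraction: float = 0.8
    synonym_species_fraction: float = 0.3
    missing_year_rate: float = 0.05
    year_range: tuple[int, int] = (1950, 2021)
    biome_bounds: tuple[float, float, float, float] = (-75.0, -15.0, -50.0, 5.0)
    level2_split: tuple[int, int] = (1, 3)   # rows x cols (west / central / east zones)
    level3_split: tuple[int, int] = (2, 2)   # per level-2 basin
    regions_per_species: tuple[int, int] = (1, 6)
    region_weights: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("open_nomenclature_rate", "synonym_use_rate", "missing_coord_rate",
                     "imprecise_coord_rate", "outside_biome_rate",
                     "dubious_species_fraction", "endemic_fraction",
                     "synonym_species_fraction", "missing_year_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species <= 0 or self.n_sources <= 0:
            raise ValueError("counts must be positive")

    def source_names(self) -> list[str]:
        names = list(_SOURCE_NAMES[: self.n_sources])
        while len(names) < self.n_sources:
            names.append(f"source{len(names)}")
        return names

    def source_counts(self) -> list[int]:
        if self.records_per_source is not None:
            if len(self.records_per_source) != self.n_sources:
                raise ValueError("records_per_source length must equal n_sources")
            return [int(n) for n in self.records_per_source]
        base = [1800, 1300, 1000, 500, 400, 200, 100, 100]
        return base[: self.n_sources]


@dataclass
class TruthLedger:
    """Ground truth for a generated dataset."""

    species_pool: list[str]
    endemic_species: list[str]
    dubious_species: list[str]
    region_composition: dict[str, set] = field(default_factory=dict)
    record_defects: dict[str, set] = field(default_factory=dict)
    first_excluding_stage: dict[str, int] = field(default_factory=dict)  # 0 = survives

    def expected_stage_exclusions(self) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0}
        for stage in self.first_excluding_stage.values():
            if stage in counts:
                counts[stage] += 1
        return counts

    @property
    def n_expected_retained(self) -> int:
        return sum(1 for s in self.first_excluding_stage.values() if s == 0)


def generate_landscape(config: GeneratorConfig) -> RegionSet:
    """Rectangular biome with a 3-level nested basin hierarchy.

    Level 1 is the whole biome; level 2 splits it into a grid of zones;
    level 3 splits each zone again.  Children partition their parent
    exactly (rectangles share edges), so areas sum across levels.
    """
    minx, miny, maxx, maxy = config.biome_bounds
    if maxx <= minx or maxy <= miny:
        raise ValueError("degenerate biome bounds")
    for rows, cols in (config.level2_split, config.level3_split):
        if rows < 1 or cols < 1:
            raise ValueError("basin split counts must be >= 1")

    regions = RegionSet()
    biome_geom = box(minx, miny, maxx, maxy)
    regions.add(RegionPolygon("biome", "biome", level=0, geometry=biome_geom,
                              area_km2=polygon_area_km2(biome_geom)))
    regions.add(RegionPolygon("b1_00", "root basin", level=1, parent_id="biome",
                              geometry=biome_geom, area_km2=polygon_area_km2(biome_geom)))

    def split(geom, rows, cols):
        gminx, gminy, gmaxx, gmaxy = geom.bounds
        dx = (gmaxx - gminx) / cols
        dy = (gmaxy - gminy) / rows
        for r in range(rows):
            for c in range(cols):
                yield r, c, box(gminx + c * dx, gminy + r * dy,
                                gminx + (c + 1) * dx, gminy + (r + 1) * dy)

    r2, c2 = config.level2_split
    for r, c, geom2 in split(biome_geom, r2, c2):
        rid2 = f"b2_{r:02d}{c:02d}"
        regions.add(RegionPolygon(rid2, f"level-2 basin ({r},{c})", level=2,
                                  parent_id="b1_00", geometry=geom2,
                                  area_km2=polygon_area_km2(geom2)))
        r3, c3 = config.level3_split
        for rr, cc, geom3 in split(geom2, r3, c3):
            rid3 = f"b3_{r:02d}{c:02d}_{rr:02d}{cc:02d}"
            regions.add(RegionPolygon(rid3, f"level-3 basin under ({r},{c})", level=3,
                                      parent_id=rid2, geometry=geom3,
                                      area_km2=polygon_area_km2(geom3)))
    return regions


def _make_epithet(rng: np.random.Generator, used: set) -> str:
    while True:
        n = int(rng.integers(3, 6))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(n))
        if word not in used:
            used.add(word)
            return word


def generate_taxonomy(config: GeneratorConfig, rng: Optional[np.random.Generator] = None
                      ) -> tuple[Taxonomy, TruthLedger]:
    """Species pool with synonyms, biome codes and IUCN categories.

    ``endemic_fraction`` of species get codes == {AM};
    ``dubious_species_fraction`` get codes without AM (they should be
    dropped by the distribution vetting); the rest get AM plus others.
    Fractions resolve to exact counts by construction.
    """
    if rng is None:
        if config.seed is None:
            raise ValueError("a seed is required for reproducible generation")
        rng = np.random.default_rng(config.seed)

    n = config.n_species
    n_dubious = int(round(config.dubious_species_fraction * n))
    n_endemic = int(round(config.endemic_fraction * (n - n_dubious)))
    other_codes = sorted(BIOME_CODES - {"AM"})
    cats = list(_IUCN_PROBS)
    probs = np.array([_IUCN_PROBS[c] for c in cats])
    probs = probs / probs.sum()

    used_epithets: set = set()
    entries = []
    names = []
    for i in range(n):
        genus = _GENUS_STEMS[i % len(_GENUS_STEMS)]
        name = f"{genus} {_make_epithet(rng, used_epithets)}"
        names.append(name)
        family, order = _FAMILIES[i % len(_FAMILIES)]
        if i < n_dubious:
            codes = set(rng.choice(other_codes, size=int(rng.integers(1, 4)), replace=False))
        elif i < n_dubious + n_endemic:
            codes = {"AM"}
        else:
            codes = {"AM"} | set(rng.choice(other_codes, size=int(rng.integers(1, 3)),
                                            replace=False))
        synonyms = set()
        if rng.random() < config.synonym_species_fraction:
            old_genus = _GENUS_STEMS[int(rng.integers(0, len(_GENUS_STEMS)))]
            syn = f"{old_genus} {_make_epithet(rng, used_epithets)}"
            synonyms.add(syn)
        entries.append(TaxonEntry(accepted_name=name, order=order, family=family,
                                  synonyms=synonyms, biome_codes=codes,
                                  iucn_category=str(rng.choice(cats, p=probs))))
    taxonomy = Taxonomy(entries)
    ledger = TruthLedger(
        species_pool=sorted(names),
        endemic_species=sorted(names[n_dubious:n_dubious + n_endemic]),
        dubious_species=sorted(names[:n_dubious]),
    )
    return taxonomy, ledger


def _sample_point(rng: np.random.Generator, geom) -> tuple[float, float]:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(1000):
        lon = float(rng.uniform(minx, maxx))
        lat = float(rng.uniform(miny, maxy))
        if geom.covers(Point(lon, lat)):
            return lon, lat
    raise RuntimeError("rejection sampling failed: polygon too thin for its bounding box")


def _sample_outside(rng: np.random.Generator, biome_geom) -> tuple[float, float]:
    minx, miny, maxx, maxy = biome_geom.bounds
    margin = 0.2 * max(maxx - minx, maxy - miny)
    outer = box(minx - margin, miny - margin, maxx + margin, maxy + margin)
    for _ in range(1000):
        lon = float(rng.uniform(outer.bounds[0], outer.bounds[2]))
        lat = float(rng.uniform(outer.bounds[1], outer.bounds[3]))
        if not biome_geom.intersects(Point(lon, lat)):
            return lon, lat
    raise RuntimeError("could not draw a point outside the biome")


def generate_occurrences(
    config: GeneratorConfig,
    landscape: RegionSet,
    taxonomy: Taxonomy,
    ledger: TruthLedger,
) -> tuple[list[OccurrenceRecord], TruthLedger]:
    """Draw occurrence records over the landscape, labelling every defect.

    Species live in contiguous runs of leaf basins (sorted by longitude),
    giving spatially structured compositions; records pick a leaf basin
    (optionally weighted), then a species from its pool, then a point by
    rejection sampling into the basin polygon.
    """
    if config.seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    leaf_level = max(landscape.levels())
    leaves = sorted(landscape.at_level(leaf_level),
                    key=lambda r: (r.geometry.centroid.x, r.region_id))
    if not leaves:
        raise ValueError("landscape has no leaf basins")
    biome_geom = landscape["biome"].geometry if "biome" in landscape else None
    if biome_geom is None:
        raise ValueError("landscape must contain a 'biome' region")

    # contiguous-run species pools per leaf basin
    species = ledger.species_pool
    lo_run, hi_run = config.regions_per_species
    pools: dict[str, list[str]] = {leaf.region_id: [] for leaf in leaves}
    for sp in species:
        run = int(rng.integers(lo_run, hi_run + 1))
        run = min(run, len(leaves))
        start = int(rng.integers(0, len(leaves) - run + 1))
        for leaf in leaves[start:start + run]:
            pools[leaf.region_id].append(sp)
    for leaf in leaves:  # every basin needs at least one species
        if not pools[leaf.region_id]:
            pools[leaf.region_id].append(species[int(rng.integers(0, len(species)))])

    weights = np.ones(len(leaves))
    if config.region_weights:
        weights = np.array([config.region_weights.get(l.region_id, 1.0) for l in leaves])
    weights = weights / weights.sum()

    records: list[OccurrenceRecord] = []
    idx = 0
    y0, y1 = config.year_range
    for source, n_records in zip(config.source_names(), config.source_counts()):
        for _ in range(n_records):
            rid = f"r{idx:07d}"
            idx += 1
            leaf = leaves[int(rng.choice(len(leaves), p=weights))]
            pool = pools[leaf.region_id]
            sp = pool[int(rng.integers(0, len(pool)))]
            entry = taxonomy.get(sp)
            defects: set = set()

            # --- name defect ---
            raw_name = sp
            if rng.random() < config.open_nomenclature_rate:
                marker = _MARKER_FORMS[int(rng.integers(0, len(_MARKER_FORMS)))]
                genus, epithet = sp.split()
                raw_name = f"{genus} {marker}" if marker == "sp." else f"{genus} {marker} {epithet}"
                defects.add("open_nomenclature")
            elif entry.synonyms and rng.random() < config.synonym_use_rate:
                raw_name = sorted(entry.synonyms)[0]
                defects.add("synonym_used")

            # --- coordinate defect ---
            lat = lon = None
            uncertainty = None
            if rng.random() < config.missing_coord_rate:
                defects.add("missing_coord")
            else:
                lon, lat = _sample_point(rng, leaf.geometry)
                if rng.random() < config.imprecise_coord_rate:
                    uncertainty = float(rng.uniform(20001.0, 100000.0))
                    defects.add("imprecise_coord")
                else:
                    uncertainty = float(rng.uniform(5.0, 15000.0))

            # --- placement defect ---
            if lat is not None and rng.random() < config.outside_biome_rate:
                lon, lat = _sample_outside(rng, biome_geom)
                defects.add("outside_biome")
            if sp in ledger.dubious_species:
                defects.add("dubious_species")

            year = None
            if rng.random() >= config.missing_year_rate:
                year = int(rng.integers(y0, y1 + 1))

            if "open_nomenclature" in defects:
                stage = 1
            elif "missing_coord" in defects or "imprecise_coord" in defects:
                stage = 2
            elif "outside_biome" in defects or "dubious_species" in defects:
                stage = 3
            else:
                stage = 0
                ledger.region_composition.setdefault(leaf.region_id, set()).add(sp)

            ledger.record_defects[rid] = defects
            ledger.first_excluding_stage[rid] = stage
            records.append(OccurrenceRecord(
                record_id=rid, source_id=source, raw_name=raw_name,
                latitude=lat, longitude=lon, coordinate_uncertainty_m=uncertainty,
                year=year,
            ))
    return records, ledger
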