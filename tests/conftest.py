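import pandas as pd
import pytest
from shapely.geometry import box

from amazodex.core import OccurrenceRecord, RegionPolygon, TaxonEntry, Taxonomy
from amazodex.diversity import IncidenceMatrix


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    return Taxonomy(
        [
            TaxonEntry(
                "Boana boans",
                family="Hylidae",
                synonyms={"Hypsiboas boans"},
                biome_codes={"AM"},
                iucn_category="LC",
            ),
            TaxonEntry(
                "Rhinella marina",
                family="Bufonidae",
                biome_codes={"AM", "CE"},
                iucn_category="LC",
            ),
            TaxonEntry(
                "Atelopus flavescens",
                family="Bufonidae",
                biome_codes={"AF", "CE"},  # no Amazon mention: vetting drops it
                iucn_category="EN",
            ),
        ]
    )


@pytest.fixture
def unit_square() -> RegionPolygon:
    geom = box(0.0, 0.0, 1.0, 1.0)
    return RegionPolygon("biome", "unit square", level=0, geometry=geom, area_km2=1.0)


def make_record(record_id="r0", name="Rhinella marina", lat=0.5, lon=0.5, **kwargs):
    return OccurrenceRecord(
        record_id=record_id,
        source_id=kwargs.pop("source_id", "gbif"),
        raw_name=name,
        latitude=lat,
        longitude=lon,
        **kwargs,
    )


@pytest.fixture
def incidence_5x5() -> IncidenceMatrix:
    """5 units x 5 species; S_obs=5, Q1=0, Q2=3 (vegan-verified fixture)."""
    data = [
        [1, 1, 0, 0, 1],
        [1, 0, 0, 0, 0],
        [0, 1, 1, 0, 0],
        [1, 1, 1, 1, 1],
        [0, 0, 0, 1, 0],
    ]
    df = pd.DataFrame(
        data,
        index=[f"u{i}" for i in range(5)],
        columns=[f"sp{i}" for i in range(5)],
    )
    return IncidenceMatrix(df)
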