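"""Domain types and file round-trips."""

import math

import pytest

from amazodex.core import FilterReport, Flag, SchemaError, TaxonEntry, Taxonomy
from amazodex.io import (
    read_occurrences,
    read_regions,
    read_taxon_table,
    write_occurrences,
    write_regions,
    write_taxon_table,
)
from amazodex.regionalization import EARTH_RADIUS_KM
from amazodex.synth import GeneratorConfig, generate_landscape
from conftest import make_record


def test_read_occurrences_clean_rows(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text(
        "occurrenceID,institutionCode,scientificName,decimalLatitude,decimalLongitude,year\n"
        "a,gbif,Boana boans,-3.5,-60.1,2001\n"
        "b,gbif,Rhinella marina,-4.0,-61.0,2002\n"
        "c,vertnet,Scinax ruber,-5.0,-62.0,2003\n"
    )
    recs = read_occurrences(p)
    assert len(recs) == 3
    assert all(not r.flags for r in recs)
    assert recs[0].latitude == -3.5 and recs[2].year == 2003


def test_read_occurrences_missing_latitude_flags(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text(
        "occurrenceID,institutionCode,scientificName,decimalLatitude,decimalLongitude\n"
        "a,gbif,Boana boans,,-60.1\n"
    )
    (rec,) = read_occurrences(p)
    assert rec.latitude is None and rec.longitude is None
    assert Flag.MISSING_COORD in rec.flags


def test_read_occurrences_dms_cell(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text(
        'occurrenceID,institutionCode,scientificName,decimalLatitude,decimalLongitude\n'
        'a,gbif,Boana boans,"3°51\'36""S",-58.25\n'
    )
    (rec,) = read_occurrences(p)
    assert rec.latitude == pytest.approx(-3.86)
    assert rec.longitude == -58.25


def test_read_occurrences_missing_mandatory_column(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("occurrenceID,decimalLatitude\na,1\n")
    with pytest.raises(SchemaError, match="scientificName"):
        read_occurrences(p)


def test_occurrence_roundtrip_preserves_fields(tmp_path):
    records = [
        make_record("a", lat=-3.123456789, lon=-60.0, year=1999,
                    coordinate_uncertainty_m=123.5),
        make_record("b", name="Boana boans", lat=None, lon=None, source_id="vertnet"),
    ]
    path = tmp_path / "out.csv"
    write_occurrences(records, path)
    back = read_occurrences(path)
    assert len(back) == len(records)
    for orig, rt in zip(records, back):
        assert rt.record_id == orig.record_id
        assert rt.source_id == orig.source_id
        assert rt.raw_name == orig.raw_name
        assert rt.year == orig.year
        if orig.latitude is None:
            assert rt.latitude is None
        else:
            assert rt.latitude == orig.latitude  # bit-for-bit via repr round-trip
            assert rt.longitude == orig.longitude


def test_taxon_table_roundtrip_and_merge(tmp_path):
    p = tmp_path / "taxa.csv"
    p.write_text(
        "accepted_name,order,family,synonyms,biome_codes,iucn\n"
        "Boana boans,Anura,Hylidae,Hypsiboas boans,AM,LC\n"
        "Boana boans,Anura,Hylidae,Hyla boans,AM|AN,LC\n"
        "Rhinella marina,Anura,Bufonidae,,AM|CE,NA\n"
    )
    tax = read_taxon_table(p)
    assert len(tax) == 2
    entry = tax.get("Boana boans")
    assert entry.synonyms == {"Hypsiboas boans", "Hyla boans"}
    assert entry.biome_codes == {"AM", "AN"}
    # paper-style "NA" (not assessed) is stored as NE
    assert tax.get("Rhinella marina").iucn_category == "NE"
    out = tmp_path / "taxa2.csv"
    write_taxon_table(tax, out)
    assert len(read_taxon_table(out)) == 2


def test_taxon_table_synonym_conflict(tmp_path):
    p = tmp_path / "taxa.csv"
    p.write_text(
        "accepted_name,synonyms,biome_codes,iucn\n"
        "Boana boans,Hypsiboas boans,AM,LC\n"
        "Boana wavrini,Hypsiboas boans,AM,LC\n"
    )
    with pytest.raises(SchemaError, match="Hypsiboas boans"):
        read_taxon_table(p)


def test_taxon_entry_rejects_self_synonym():
    with pytest.raises(ValueError):
        TaxonEntry("Boana boans", synonyms={"Boana boans"})


def test_regions_unit_square_and_default_level(tmp_path):
    p = tmp_path / "r.geojson"
    p.write_text(
        '{"type": "FeatureCollection", "features": [{"type": "Feature",'
        '"properties": {"region_id": "sq", "name": "square"},'
        '"geometry": {"type": "Polygon", "coordinates":'
        '[[[0,0],[1,0],[1,1],[0,1],[0,0]]]}}]}'
    )
    regions = read_regions(p)
    sq = regions["sq"]
    assert sq.level == 0  # missing level defaults to 0
    assert len(sq.geometry.exterior.coords) == 5


def test_equatorial_degree_square_area(tmp_path):
    """1x1 degree at the equator matches the spherical zone formula within 0.5%."""
    p = tmp_path / "r.geojson"
    p.write_text(
        '{"type": "FeatureCollection", "features": [{"type": "Feature",'
        '"properties": {"region_id": "eq", "level": 1},'
        '"geometry": {"type": "Polygon", "coordinates":'
        '[[[0,0],[1,0],[1,1],[0,1],[0,0]]]}}]}'
    )
    area = read_regions(p)["eq"].area_km2
    expected = EARTH_RADIUS_KM**2 * math.radians(1.0) * (math.sin(math.radians(1.0)) - 0.0)
    assert area == pytest.approx(expected, rel=0.005)
    assert area == pytest.approx(12364, rel=0.005)


def test_region_roundtrip(tmp_path):
    landscape = generate_landscape(GeneratorConfig(seed=3))
    path = tmp_path / "l.geojson"
    write_regions(landscape, path)
    back = read_regions(path)
    assert len(back) == len(landscape)
    for region in landscape:
        rt = back[region.region_id]
        assert rt.level == region.level
        assert rt.parent_id == region.parent_id
        assert rt.area_km2 == pytest.approx(region.area_km2, rel=1e-9)
        assert rt.geometry.equals(region.geometry)


def test_filter_report_identity_and_double_stage():
    report = FilterReport(100)
    report.record_stage("taxonomic", 20)
    report.record_stage("geographic", 30)
    assert report.n_retained == 50
    assert report.check_identity()
    with pytest.raises(ValueError):
        report.record_stage("taxonomic", 1)
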