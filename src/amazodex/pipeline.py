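"""End-to-end orchestration: synth -> filter -> regionalize -> diversity -> report.

A run is driven by a config dict (YAML on disk), executes the filters in
their fixed order (taxonomic, then geographic, then biogeographic —
reported exclusion counts are order-dependent), round-trips every stage
through files so that each stage's outputs are valid inputs to the next
stage's readers, and ends with a machine-readable manifest (config hash,
seed, per-stage counts, output checksums).  Identical config + seed
reproduces identical counts and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .biogeography import apply_biogeographic_filter
from .core import FilterReport, RegionSet
from .diversity import (
    accumulation_curve,
    build_incidence,
    incidence_by_year,
    jaccard_similarity,
    jackknife2,
    poisson_glm,
    richness_endemism,
    upgma_cluster,
    cut,
    dendrogram_to_newick,
)
from .geography import apply_geographic_filter
from .io import (
    read_occurrences,
    read_regions,
    read_taxon_table,
    write_occurrences,
    write_regions,
    write_taxon_table,
)
from .regionalization import assign_records, build_grid, select_subbasins
from .reporting import (
    filter_accounting,
    iucn_summary,
    source_complementarity,
    temporal_summary,
)
from .synth import GeneratorConfig, generate_landscape, generate_occurrences, generate_taxonomy
from .taxonomy import apply_taxonomic_filter

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "run_synth"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},  # GeneratorConfig overrides
    "taxonomy": {"policy": "strict"},
    "geography": {"max_radius_km": 20.0, "drop_zero_zero": True},
    "biogeography": {"target_code": "AM"},
    "regionalization": {"mode": "auto", "min_area_km2": 30000.0, "cell_size_km": 50.0},
    "diversity": {
        "cut_similarity": 0.40,
        "glm_covariate": "log_area",
        "accumulation_method": "exact",
        "n_perm": 100,
    },
    "report": {"site_decimals": 4},
}


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_synth(config: dict, out_dir: Union[str, Path]):
    """Generate and write the synthetic landscape, taxonomy and occurrences."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_cfg = GeneratorConfig(seed=config["seed"], **config.get("synth", {}))
    landscape = generate_landscape(gen_cfg)
    taxonomy, ledger = generate_taxonomy(gen_cfg)
    records, ledger = generate_occurrences(gen_cfg, landscape, taxonomy, ledger)
    write_regions(landscape, out_dir / "landscape.geojson")
    write_taxon_table(taxonomy, out_dir / "taxa.csv")
    write_occurrences(records, out_dir / "occurrences.csv")
    (out_dir / "truth.json").write_text(
        json.dumps(
            {
                "species_pool": ledger.species_pool,
                "endemic_species": ledger.endemic_species,
                "dubious_species": ledger.dubious_species,
                "expected_stage_exclusions": ledger.expected_stage_exclusions(),
                "n_expected_retained": ledger.n_expected_retained,
            },
            sort_keys=True,
            indent=1,
        ),
        encoding="utf-8",
    )
    return landscape, taxonomy, records, ledger


def run_pipeline(config: Optional[dict] = None, out_dir: Union[str, Path] = "amazodex_out") -> dict:
    """Run the whole pipeline; returns the manifest dict (also written to disk)."""
    config = _merge(DEFAULT_CONFIG, config)
    if config.get("seed") is None:
        raise ValueError("config requires a seed")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    counts: dict[str, int] = {}

    # --- stage: synthesize (or load) inputs, then round-trip through files ---
    stage = "synth"
    try:
        if "inputs" in config:
            occ_path = Path(config["inputs"]["occurrences"])
            taxa_path = Path(config["inputs"]["taxa"])
            regions_path = Path(config["inputs"]["regions"])
            ledger = None
        else:
            run_synth(config, out_dir)
            occ_path = out_dir / "occurrences.csv"
            taxa_path = out_dir / "taxa.csv"
            regions_path = out_dir / "landscape.geojson"
            ledger = None  # re-read from files below; truth.json persists separately
        records = read_occurrences(occ_path)
        taxonomy = read_taxon_table(taxa_path)
        landscape = read_regions(regions_path)
        counts["initial"] = len(records)

        # --- filters, in the fixed order ---
        stage = "taxonomic_filter"
        policy = config["taxonomy"].get("policy", "strict")
        kept1, excl1, _ = apply_taxonomic_filter(records, taxonomy, policy=policy)
        counts["excluded_taxonomic"] = len(excl1)

        stage = "geographic_filter"
        geo = config["geography"]
        kept2, excl2, _ = apply_geographic_filter(
            kept1, max_radius_km=geo["max_radius_km"], drop_zero_zero=geo["drop_zero_zero"]
        )
        counts["excluded_geographic"] = len(excl2)

        stage = "biogeographic_filter"
        biome = landscape["biome"]
        kept3, excl3, _, dropped_species = apply_biogeographic_filter(
            kept2, biome, taxonomy, target_code=config["biogeography"]["target_code"]
        )
        counts["excluded_biogeographic"] = len(excl3)
        counts["retained"] = len(kept3)

        report = FilterReport(counts["initial"])
        report.record_stage("taxonomic", len(excl1))
        report.record_stage("geographic", len(excl2))
        report.record_stage("biogeographic", len(excl3))
        accounting = filter_accounting(report)
        accounting.to_csv(out_dir / "filter_accounting.csv", index=False)
        write_occurrences(kept3, out_dir / "curated.csv")
        (out_dir / "dropped_species.csv").write_text(
            "species\n" + "".join(f"{s}\n" for s in dropped_species), encoding="utf-8"
        )

        # --- regionalization ---
        stage = "regionalization"
        reg_cfg = config["regionalization"]
        basin_hierarchy = RegionSet([r for r in landscape if r.level >= 1])
        basins = select_subbasins(
            basin_hierarchy,
            mode=reg_cfg["mode"],
            min_area_km2=reg_cfg["min_area_km2"],
            biome=biome,
        )
        write_regions(basins, out_dir / "basins.geojson")
        grid = build_grid(biome, cell_size_km=reg_cfg["cell_size_km"])
        basin_assign, basin_slivers = assign_records(kept3, basins)
        grid_assign, grid_slivers = assign_records(kept3, grid)
        counts["basins"] = len(basins)
        counts["grid_cells"] = len(grid)
        counts["unassigned_basin"] = len(basin_slivers)

        # --- diversity ---
        stage = "diversity"
        div_cfg = config["diversity"]
        matrix = build_incidence(basin_assign, kept3, unit_ids=[b.region_id for b in basins])
        re_table = richness_endemism(matrix, taxonomy,
                                     target_code=config["biogeography"]["target_code"])
        re_table.to_csv(out_dir / "basin_richness_endemism.csv", index_label="basin")
        grid_matrix = build_incidence(grid_assign, kept3)
        grid_richness = richness_endemism(grid_matrix, taxonomy)
        grid_richness.to_csv(out_dir / "grid_richness.csv", index_label="cell")

        diversity_stats: dict = {}
        if matrix.m >= 2:
            sim = jaccard_similarity(matrix)
            sim.to_csv(out_dir / "jaccard_similarity.csv")
            dendro = upgma_cluster(sim)
            (out_dir / "dendrogram.newick").write_text(
                dendrogram_to_newick(dendro), encoding="utf-8"
            )
            groups = cut(dendro, min_similarity=div_cfg["cut_similarity"])
            diversity_stats["n_groups"] = len(groups)

        year_matrix = incidence_by_year(kept3)
        if year_matrix.m >= 2:
            curve = accumulation_curve(
                year_matrix,
                method=div_cfg["accumulation_method"],
                n_perm=div_cfg["n_perm"],
                seed=config["seed"],
            )
            curve.to_csv(out_dir / "accumulation.csv", index=False)
            diversity_stats["S_obs"] = year_matrix.S_obs
            diversity_stats["jackknife2"] = jackknife2(year_matrix)

        if matrix.m >= 3:
            fit = poisson_glm(
                re_table["richness"],
                [basins[b].area_km2 for b in matrix.units],
                covariate=div_cfg["glm_covariate"],
            )
            diversity_stats["glm"] = dataclasses.asdict(fit)

        # --- reports ---
        stage = "report"
        rep_cfg = config["report"]
        species_final = sorted({r.accepted_name or r.raw_name for r in kept3})
        cat_table, fam_table = iucn_summary(taxonomy, species_final)
        cat_table.to_csv(out_dir / "iucn_categories.csv", index=False)
        fam_table.to_csv(out_dir / "iucn_families.csv", index=False)
        temporal_summary(kept3).to_csv(out_dir / "temporal.csv", index=False)
        source_complementarity(kept3, site_decimals=rep_cfg["site_decimals"]).to_csv(
            out_dir / "sources.csv", index=False
        )
        counts["species_retained"] = len(species_final)
    except Exception as err:
        partial = {
            "failed_stage": stage,
            "error": str(err),
            "counts": counts,
            "config_hash": _config_hash(config),
        }
        (out_dir / "manifest.json").write_text(json.dumps(partial, indent=1), encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    outputs = sorted(
        p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config["seed"],
        "config_hash": _config_hash(config),
        "counts": counts,
        "diversity": diversity_stats,
        "checksums": {name: _checksum(out_dir / name) for name in outputs},
        "started": t_start,
        "elapsed_s": time.time() - t_start,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float), encoding="utf-8"
    )
    return manifest
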