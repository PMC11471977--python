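# Methods

## The curation model

The pipeline treats database assembly as three sequential record-level
filters whose counts are order-dependent and therefore fixed:
taxonomic, then geographic, then biogeographic. Each record is charged
to exactly one bucket (retained, or excluded at the first failing
stage), and the accounting identity
`n_initial = n_retained + Σ stage exclusions` is checked — never assumed
— whenever a report is produced.

**Taxonomic filter.** A verbatim name is parsed into genus, epithet,
infraspecific tokens, an optional open-nomenclature marker and an
author-year remnant. Markers (`cf`, `gr`, `aff`, `sp`, plus the `spp`,
`sp. nov.`, `n. sp.` and `?` variants, extensible by config) are
detected case-insensitively at any position after the genus, with or
without a trailing period; a genus-only record parses as `sp`.
Subspecies trinomials collapse to the binomial because all downstream
statistics are species-level. Clean binomials resolve by exact lookup,
accepted names before the synonym map; the synonym map is injective by
construction (a synonym under two accepted names is a schema error).
Voucher re-confirmation of uncertain records cannot be reproduced
offline, so the filter instead offers a policy switch: `strict`
(default) also excludes clean names absent from the reference table,
`lenient` keeps them flagged. The author-remnant heuristic treats a
capital-then-lowercase token after the genus as the start of an author
string, so all-caps data-entry names still parse as epithets.

**Geographic filter.** DMS strings convert as `D + M/60 + S/3600` with
sign from a hemisphere letter or a leading minus (conflicting signs are
parse errors, as are minutes or seconds ≥ 60); plain decimals pass
through. Outcomes are assigned with a fixed precedence — missing,
out-of-range, (0, 0), administrative precision, too imprecise, ok — so
each record gets exactly one. The imprecision threshold is *strictly*
greater than 20 km (a stated radius of exactly 20,000 m is kept).
Records with coordinates but no uncertainty metadata are kept when their
described precision is point / locality / unknown: exclusion is by
described precision, not by absent metadata. (0, 0) is dropped by
default as a data-entry artifact; both choices are config keys. Input
coordinates are assumed WGS84 already; no datum shift is attempted.

**Biogeographic filter.** Containment uses the closed-boundary
convention (edge points inside), since the peripheral-record concern is
already handled by the 20 km rule. Distribution vetting collapses the
two-step expert-plus-platform review into a single data table of biome
codes: a species whose codes never mention the target biome (default
`AM`) loses *all* its records, wherever they fall. Species absent from
the reference table are kept with a flag rather than silently dropped.
The biome polygon is used unbuffered.

## Regionalization

Basin selection (`auto` mode) descends each branch of the nested
hierarchy while *every* child of the current node exceeds the area
threshold (default 30,000 km²), otherwise stops at the node. Stopping on
the whole sibling set keeps the selection a partition — mixing a
qualifying child with its too-small sibling would otherwise create
overlaps or gaps. `zonal` mode instead takes an explicit hierarchy level
per longitudinal zone polygon, for workflows where the level-per-zone
choice is made by eye. Selected basins are clipped to the biome and
their areas recomputed.

Areas are spherical, not ellipsoidal: polygons are densified to 0.05°
edges, mapped through a cylindrical equal-area projection
(x = Rλ, y = R sin φ, R = 6371 km) and measured with the planar
shoelace formula. The flattening error (≈ 0.1–0.3 %) is far below the
granularity at which a 30,000 km² threshold distinguishes basins. The
richness grid uses the same projection family with the standard parallel
at the biome centroid, tiled from the projected bounding-box minimum
corner; cells are exactly `cell_size_km²` in area by construction.
Records on a shared unit border are assigned to the lowest region id —
an arbitrary but deterministic tie-break, tested under both insertion
orders.

## Diversity statistics

The incidence matrix stores booleans (presence = at least one record);
duplicates collapse on construction. Endemism is the strict rule
`biome_codes == {AM}` — a species also documented elsewhere is not
endemic. Jaccard similarity of two empty units is defined as 1 (they
are indistinguishable), with a warning, since empty grid cells can
legitimately occur. Clustering is UPGMA (average linkage) on `1 − J`:
the standard choice for compositional dendrograms, exposed in config;
merge heights are monotone for average linkage. The threshold cut
connects leaves through merges at distance strictly below
`1 − min_similarity`, so a merge exactly at the threshold does *not*
join its groups.

The exact accumulation curve is the hypergeometric expectation
`E[S(t)] = Σᵢ [1 − C(m − mᵢ, t)/C(m, t)]`; the permutation variant
averages cumulative richness over seeded random unit orders and reports
2.5/97.5 % quantiles. Years serve as sampling units for the temporal
curve; records without a year are excluded from the accumulation only.
The jackknife estimators are the standard incidence-based forms
(`jackknife2 = S_obs + Q1(2m−3)/m − Q2(m−2)²/(m(m−1))`), undefined for
m < 2. Both were cross-checked against vegan (`specpool`,
`specaccum(method="exact")`) on small fixtures, and the permutation
curve against the closed form at Monte-Carlo tolerance.

The richness–area model is a Poisson log-link GLM fitted by IRLS
(statsmodels) with z statistics from the observed information. The
covariate defaults to log(area) — the conventional species–area form —
with a raw-area mode available, since the source workflow does not state
its transform.

## The synthetic generator

The generator emulates what the real multi-platform pulls look like
*after* aggregation: several sources of unequal size, open-nomenclature
and synonym name variants, missing and imprecise coordinates, points
outside the biome, and species with no documented biome distribution.
The landscape is a rectangular biome (default 25° × 20°, area ≈ 5.6
million km²) carrying a 3-level nested basin hierarchy built by exact
rectangular subdivision (default 1 → 3 → 12 basins), so children
partition parents to within densification error. Species occupy
contiguous runs of leaf basins ordered by longitude, giving spatially
structured compositions; points are drawn by rejection sampling into the
basin polygon.

Defects apply independently per record in a fixed order — name, then
coordinates, then placement — and the ledger records the *first* stage
that should exclude each record, mirroring sequential filtering. Filter
tests therefore compare against exact labels, not rates. Default rates
(24 % open nomenclature; 45 % missing and 7 % imprecise coordinates;
25 % outside-biome moves; 9 % of species dubious; 15 % synonym usage
among clean names) were chosen once so that the per-stage exclusion
shares of a default run land near the ~24 / ~39 / ~18 % profile
reported for real aggregated amphibian data, with roughly a fifth of
records surviving; they are configuration, not fitted values. Dubious
and endemic species fractions resolve to exact counts by construction.

What the generator does **not** emulate: spatial sampling bias fields
(roads, rivers, cities), cross-platform duplicate records, taxonomic
concept drift over time, or coordinate rounding artifacts. Passing
tests therefore demonstrate that the pipeline recovers *labelled* defect
structure exactly and its statistics match their closed forms — not that
real aggregated data contain no other failure modes. The optional
exact-duplicate collapse (same name, coordinates, year, source) is
exposed for real data but no cross-source inference is attempted.

## Numerical choices and degenerate inputs

- Seeds are mandatory for every stochastic operation; the pipeline
  manifest records config hash, per-stage counts and output checksums,
  and identical seed + config reproduces identical bytes.
- Floats are written with `repr` round-trip formatting, so clean CSV
  round-trips preserve coordinates bit for bit.
- IRLS runs to tolerance 1e−10 with a 100-iteration cap; non-convergence
  raises with the fit diagnostics rather than returning a partial fit.
- Degenerate cases are errors, not silent results: jackknife2 with
  m < 2, pairwise similarity with one unit, percent with a zero
  denominator, a landscape whose basin counts cannot tile the biome.
- `percent` rounds half-away-from-zero (1/16 → 6.3 %), matching
  hand-rounded report arithmetic rather than banker's rounding.
- The site definition for source summaries (coordinates rounded to 4
  decimals ≈ 11 m) is a documented stand-in for an unstated convention
  and is a config key.

## Problem sizes

The default test and demonstration configurations use 5,000–10,000
records, 60 species, 12 leaf basins and ~2,500 grid cells; these sizes
exercise every code path while keeping a full run in seconds.
Acceptance-style checks use 10⁴ records for ledger recovery, 10³ random
point-in-polygon cases against a winding-number oracle, 500-permutation
accumulation curves on 10 × 20 matrices, and n = 500 GLM recovery
simulations.

## Known limitations

- Name matching is exact after normalization; misspellings are not
  fuzzy-matched and will count as unresolved.
- The basin hierarchy must nest cleanly; the selector does not repair
  topologically inconsistent inputs beyond `make_valid` at read time.
- Richness–area fits on few, similarly sized basins are weakly
  identified; the z statistic is reported but should be read with the
  unit count in mind.
- No gazetteer geocoding, datum shifts, shapefile parsing, or live
  platform clients: inputs are delimited text and GeoJSON.
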