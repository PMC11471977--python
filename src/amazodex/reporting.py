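"""Summary products: filter accounting, IUCN tallies, temporal and source summaries.

Percentages are rounded half-away-from-zero so that shares printed in
reports match conventional hand-rounded arithmetic (e.g. 39.459 -> 39.5).
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .core import FilterReport, OccurrenceRecord, THREATENED, Taxonomy

__all__ = [
    "percent",
    "filter_accounting",
    "iucn_summary",
    "temporal_summary",
    "source_complementarity",
]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def filter_accounting(report: FilterReport, decimals: int = 1) -> pd.DataFrame:
    """Tabulate per-stage exclusions with shares of the initial count.

    Raises ``ValueError`` when the conservation identity
    initial = retained + sum(exclusions) is violated.
    """
    if not report.check_identity():
        raise ValueError(
            "accounting identity violated: "
            f"initial {report.n_initial} != retained {report.n_retained} "
            f"+ excluded {report.total_excluded}"
        )
    rows = []
    for stage, n in report.excluded.items():
        rows.append(
            {
                "stage": stage,
                "excluded": n,
                "share_pct": percent(n, report.n_initial, decimals),
            }
        )
    rows.append(
        {
            "stage": "retained",
            "excluded": report.n_retained,
            "share_pct": percent(report.n_retained, report.n_initial, decimals),
        }
    )
    return pd.DataFrame(rows)


def iucn_summary(
    taxonomy: Taxonomy,
    species_list: Iterable[str],
    flag_threshold_pct: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category species counts and per-family threatened shares.

    Threatened = {CR, EN, VU}.  A family is flagged when its threatened
    share strictly exceeds ``flag_threshold_pct``.  DD and NE stay as
    their own rows and are never pooled into threatened.  Returns
    (category table, family table).
    """
    species = sorted(set(species_list))
    cats = Counter()
    fam_total = Counter()
    fam_threat = Counter()
    for sp in species:
        entry = taxonomy.get(sp)
        cat = entry.iucn_category if entry is not None else "NE"
        cats[cat] += 1
        family = entry.family if entry is not None and entry.family else "unknown"
        fam_total[family] += 1
        if cat in THREATENED:
            fam_threat[family] += 1
    total = len(species)
    cat_rows = [
        {
            "category": c,
            "n_species": cats.get(c, 0),
            "share_pct": percent(cats.get(c, 0), total, 1) if total else 0.0,
        }
        for c in ("CR", "EN", "VU", "NT", "LC", "DD", "NE")
    ]
    fam_rows = []
    for family in sorted(fam_total):
        share = percent(fam_threat[family], fam_total[family], 1)
        fam_rows.append(
            {
                "family": family,
                "n_species": fam_total[family],
                "n_threatened": fam_threat[family],
                "threatened_pct": share,
                "flagged": share > flag_threshold_pct,
            }
        )
    return pd.DataFrame(cat_rows), pd.DataFrame(fam_rows)


def temporal_summary(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    """Per-decade record counts and cumulative species counts.

    Decade = floor(year / 10) * 10.  Records without a year are reported
    in a separate ``undated`` row (decade = -1) and excluded from the
    cumulative species count.
    """
    dated: dict[int, list[str]] = {}
    n_undated = 0
    for rec in records:
        if rec.year is None:
            n_undated += 1
            continue
        decade = (rec.year // 10) * 10
        dated.setdefault(decade, []).append(rec.accepted_name or rec.raw_name)
    rows = []
    seen: set[str] = set()
    for decade in sorted(dated):
        names = dated[decade]
        seen |= set(names)
        rows.append(
            {
                "decade": decade,
                "n_records": len(names),
                "n_species": len(set(names)),
                "cumulative_species": len(seen),
            }
        )
    if n_undated:
        rows.append(
            {"decade": -1, "n_records": n_undated, "n_species": 0, "cumulative_species": len(seen)}
        )
    return pd.DataFrame(rows, columns=["decade", "n_records", "n_species", "cumulative_species"])


def source_complementarity(
    records: Iterable[OccurrenceRecord], site_decimals: int = 4
) -> pd.DataFrame:
    """Per-source record / species / site tallies plus greedy marginal gains.

    A site is a unique (lon, lat) pair rounded to ``site_decimals``
    decimal places (~11 m at 4).  The ``marginal_species`` column lists
    each source's species gain in a greedy ordering by that gain, so the
    gains sum to the total species richness across sources.
    """
    by_source: dict[str, dict] = {}
    for rec in records:
        src = rec.source_id or "unknown"
        entry = by_source.setdefault(src, {"n_records": 0, "species": set(), "sites": set()})
        entry["n_records"] += 1
        entry["species"].add(rec.accepted_name or rec.raw_name)
        if rec.has_coordinates:
            entry["sites"].add(
                (round(rec.longitude, site_decimals), round(rec.latitude, site_decimals))
            )

    gains: dict[str, int] = {}
    rank: dict[str, int] = {}
    covered: set = set()
    remaining = set(by_source)
    position = 0
    while remaining:
        # max() keeps the first of sorted() on ties -> deterministic ordering
        best = max(sorted(remaining), key=lambda s: len(by_source[s]["species"] - covered))
        gains[best] = len(by_source[best]["species"] - covered)
        rank[best] = position
        covered |= by_source[best]["species"]
        remaining.discard(best)
        position += 1

    rows = []
    for src in sorted(by_source, key=lambda s: rank[s]):
        entry = by_source[src]
        rows.append(
            {
                "source": src,
                "n_records": entry["n_records"],
                "n_species": len(entry["species"]),
                "n_sites": len(entry["sites"]),
                "marginal_species": gains[src],
                "greedy_rank": rank[src],
            }
        )
    return pd.DataFrame(rows)
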