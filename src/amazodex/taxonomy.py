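"""Taxonomic refinement (filter 1): open nomenclature and synonym resolution.

Records whose verbatim name carries an open-nomenclature qualifier —
``cf.`` (confer), ``gr.`` (group), ``aff.`` (affine), ``sp.`` (species
uncertain) — are excluded; the remaining names are resolved against the
taxon reference table, grouping synonyms under the current valid name.
Subspecies trinomials collapse to the binomial, since downstream
statistics are species-level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import FilterReport, Flag, OccurrenceRecord, Taxonomy

__all__ = [
    "NameParse",
    "DEFAULT_MARKERS",
    "parse_scientific_name",
    "resolve_synonym",
    "apply_taxonomic_filter",
]

#: Open-nomenclature qualifiers treated as taxonomic uncertainty.  Each
#: maps its written variants (case-insensitive, optional trailing period)
#: to the canonical marker.  Extendable via the ``extra_markers`` argument.
DEFAULT_MARKERS = {
    "cf": "cf",
    "gr": "gr",
    "aff": "aff",
    "sp": "sp",
    "spp": "sp",
    "nov": "sp",   # "sp. nov." / "n. sp." fragments
    "n": "sp",
    "?": "sp",
}

_SUBGENUS_RE = re.compile(r"^\([A-ZÀ-Þ][\w-]*\)$")


@dataclass
class NameParse:
    genus: str = ""
    epithet: Optional[str] = None
    infraspecific: list = field(default_factory=list)
    marker: Optional[str] = None  # one of cf / gr / aff / sp, or None
    author: str = ""

    @property
    def binomial(self) -> Optional[str]:
        if self.genus and self.epithet:
            return f"{self.genus} {self.epithet}"
        return None


def _normalize_token(token: str) -> str:
    return token.rstrip(".").lower()


def parse_scientific_name(raw: str, extra_markers: Optional[dict] = None) -> NameParse:
    """Parse a verbatim scientific-name string.

    Detects open-nomenclature markers at any position after the genus,
    case-insensitively, with or without a trailing period; strips a
    parenthesized subgenus and an author–year suffix.  A single-token
    input (genus only) parses with marker ``sp``.
    """
    if not raw or not str(raw).strip():
        raise ValueError("empty scientific name")
    markers = dict(DEFAULT_MARKERS)
    if extra_markers:
        markers.update(extra_markers)
    parse = NameParse()
    tokens = str(raw).split()
    # drop a parenthesized subgenus right after the genus
    if len(tokens) > 1 and _SUBGENUS_RE.match(tokens[1]):
        tokens = [tokens[0]] + tokens[2:]
    # the author-year remnant starts at the first capitalized (or
    # parenthesized) token after the genus that is not a marker form
    # (capital-then-lowercase, so all-caps data-entry names stay epithets)
    for i, tok in enumerate(tokens[1:], start=1):
        is_author_like = tok.startswith("(") or (
            len(tok) > 1 and tok[0].isupper() and tok[1].islower()
        )
        if is_author_like and _normalize_token(tok) not in markers:
            parse.author = " ".join(tokens[i:])
            tokens = tokens[:i]
            break

    parse.genus = tokens[0].rstrip(".").capitalize()
    rest = tokens[1:]

    epithet_tokens: list[str] = []
    for tok in rest:
        key = _normalize_token(tok)
        if key in markers:
            canonical = markers[key]
            # keep the most specific marker encountered first
            if parse.marker is None:
                parse.marker = canonical
            continue
        epithet_tokens.append(tok.lower())

    if epithet_tokens:
        parse.epithet = epithet_tokens[0]
        parse.infraspecific = epithet_tokens[1:]
    elif parse.marker is None:
        # genus-only record: species unknown
        parse.marker = "sp"
    return parse


def resolve_synonym(binomial: str, taxonomy: Taxonomy) -> Optional[str]:
    """Resolve a clean binomial to its accepted name, or None if unresolved.

    Exact match on accepted names takes precedence over the synonym map.
    """
    if binomial in taxonomy:
        return binomial
    return taxonomy.synonym_map.get(binomial)


def apply_taxonomic_filter(
    records: Iterable[OccurrenceRecord],
    taxonomy: Taxonomy,
    policy: str = "strict",
    extra_markers: Optional[dict] = None,
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]], FilterReport]:
    """Filter 1: exclude open-nomenclature records and resolve names.

    ``policy="strict"`` also excludes clean binomials absent from the
    reference table; ``policy="lenient"`` keeps them flagged (standing in
    for voucher re-confirmation, which is not possible offline).
    Retained records carry ``accepted_name``.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    records = list(records)
    retained: list[OccurrenceRecord] = []
    excluded: list[tuple[OccurrenceRecord, str]] = []
    for rec in records:
        parse = parse_scientific_name(rec.raw_name, extra_markers=extra_markers)
        if parse.marker is not None:
            rec.flags.add(Flag.OPEN_NOMENCLATURE)
            excluded.append((rec, f"open_nomenclature:{parse.marker}"))
            continue
        accepted = resolve_synonym(parse.binomial, taxonomy)
        if accepted is None:
            rec.flags.add(Flag.UNRESOLVED_NAME)
            if policy == "strict":
                excluded.append((rec, "unresolved_name"))
                continue
            rec.accepted_name = parse.binomial
        else:
            if accepted != parse.binomial:
                rec.flags.add(Flag.SYNONYM_RESOLVED)
            rec.accepted_name = accepted
        retained.append(rec)
    report = FilterReport(len(records))
    n_species = len({r.accepted_name for r in retained})
    report.record_stage("taxonomic", len(excluded), n_species)
    return retained, excluded, report
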