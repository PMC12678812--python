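"""Vocabulary and date standardization with matched/unmatched reporting.

Status and habitat terms are standardized through user-editable translation
tables (one per field). Every lookup — hit or miss — is tallied, and the
misses are exported per field per run so a curator can check how and
whether each record was translated. An unmatched term never removes a
record: the field is simply left empty.

First-record dates arrive in many dialects. The grammar implemented here
is explicit and deliberately small:

* ``YYYY``                      -> that year
* ``YYYY-YYYY`` / ``YYYY–YYYY`` -> arithmetic mean of the two years,
  truncated toward the earlier year when the mean is not an integer
* ISO dates ``YYYY-MM-DD`` / ``YYYY-MM``                -> the year
* ``c. YYYY`` / ``ca. YYYY``    -> the year (circa prefix stripped)
* ``YYYYs``                     -> first year of the decade

Anything else is reported as unparseable and the field stays empty. Years
outside the plausibility window (default 1000..current year) are reported
rather than silently dropped.
"""

from __future__ import annotations

import csv
import datetime
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from sinas._text import normalize
from sinas.data_model import SEP, FIXED_VOCABULARIES, PATHWAY_TERMS, ControlledVocabulary

YEAR_MIN = 1000

_RE_YEAR = re.compile(r"^(\d{4})$")
_RE_RANGE = re.compile(r"^(\d{4})\s*[-–]\s*(\d{4})$")
_RE_ISO = re.compile(r"^(\d{4})-(\d{1,2})(?:-(\d{1,2}))?$")
_RE_CIRCA = re.compile(r"^c(?:a)?\.?\s+(\d{4})$", re.IGNORECASE)
_RE_DECADE = re.compile(r"^(\d{4})s$", re.IGNORECASE)


@dataclass
class TermMatchReport:
    """Accumulates per-field match/mismatch tallies for one run."""

    matched: Counter = None  # keys (field, source, verbatim, canonical)
    unmatched: Counter = None  # keys (field, source, verbatim)

    def __post_init__(self) -> None:
        self.matched = Counter() if self.matched is None else self.matched
        self.unmatched = Counter() if self.unmatched is None else self.unmatched

    def record_match(self, field: str, source: str, verbatim: str, canonical: str) -> None:
        self.matched[(field, source, verbatim, canonical)] += 1

    def record_miss(self, field: str, source: str, verbatim: str) -> None:
        self.unmatched[(field, source, verbatim)] += 1

    def unmatched_frame(self) -> pd.DataFrame:
        rows = [
            {"field": f, "source": s, "verbatim": v, "count": n}
            for (f, s, v), n in sorted(self.unmatched.items())
        ]
        return pd.DataFrame(rows, columns=["field", "source", "verbatim", "count"])

    def matched_frame(self) -> pd.DataFrame:
        rows = [
            {"field": f, "source": s, "verbatim": v, "canonical": c, "count": n}
            for (f, s, v, c), n in sorted(self.matched.items())
        ]
        return pd.DataFrame(rows, columns=["field", "source", "verbatim", "canonical", "count"])


def load_vocabulary(path: str | Path, field_name: str) -> ControlledVocabulary:
    """Load one translation table: a delimited file with columns
    ``canonical`` and ``variant`` (one variant per row; the canonical term
    itself need not be listed)."""
    variant_map: dict[str, str] = {}
    canonical_terms: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            canonical = row["canonical"].strip()
            canonical_terms.add(canonical)
            variant = row.get("variant", "").strip()
            if variant:
                variant_map[normalize(variant)] = canonical
    if field_name in FIXED_VOCABULARIES:
        canonical_terms |= set(FIXED_VOCABULARIES[field_name])
    elif field_name == "pathway":
        canonical_terms |= set(PATHWAY_TERMS)
    return ControlledVocabulary(field_name, frozenset(canonical_terms), variant_map)


def standardize_term(
    field_name: str,
    verbatim: str,
    vocabulary: ControlledVocabulary,
    report: TermMatchReport | None = None,
    source: str = "",
) -> str | None:
    """Translate one verbatim status term; ``None`` when it has no entry.

    A miss leaves the field empty but the record survives; the verbatim
    term is added to the unmatched report.
    """
    if vocabulary.field_name != field_name:
        raise ValueError(f"vocabulary is for '{vocabulary.field_name}', not '{field_name}'")
    if verbatim.strip() == "":
        return None
    canonical = vocabulary.lookup(verbatim)
    if report is not None:
        if canonical is None:
            report.record_miss(field_name, source, verbatim)
        else:
            report.record_match(field_name, source, verbatim, canonical)
    return canonical


def standardize_habitat(
    verbatim: str,
    vocabulary: ControlledVocabulary,
    report: TermMatchReport | None = None,
    source: str = "",
    delimiter: str = ";",
) -> str:
    """Standardize a possibly multi-valued habitat cell.

    Each delimited token is translated independently; the result is the
    deduplicated, alphabetically sorted, ``"; "``-joined subset of the
    habitat vocabulary ('' when nothing matches). Habitat describes the
    taxon, not any one location.
    """
    hits: set[str] = set()
    for token in verbatim.split(delimiter):
        if token.strip() == "":
            continue
        canonical = standardize_term("habitat", token, vocabulary, report, source)
        if canonical is not None:
            hits.add(canonical)
    return SEP.join(sorted(hits))


def standardize_event_date(
    verbatim: str,
    report: TermMatchReport | None = None,
    source: str = "",
    year_max: int | None = None,
) -> int | None:
    """Reduce a verbatim first-record date to a single integer year.

    Ranges take the arithmetic mean of their two years; a half-year mean is
    truncated toward the earlier year, consistent with the downstream
    earliest-record preference. Unparseable or implausible values return
    ``None`` and are reported.
    """
    if year_max is None:
        year_max = datetime.date.today().year
    text = verbatim.strip()
    if text == "":
        return None

    year: int | None = None
    if m := _RE_YEAR.match(text):
        year = int(m.group(1))
    elif m := _RE_RANGE.match(text):
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo <= hi:
            year = (lo + hi) // 2  # floor of the mean: truncate toward the earlier year
    elif m := _RE_ISO.match(text):
        if int(m.group(2)) <= 12 and (m.group(3) is None or int(m.group(3)) <= 31):
            year = int(m.group(1))
    elif m := _RE_CIRCA.match(text):
        year = int(m.group(1))
    elif m := _RE_DECADE.match(text):
        year = int(m.group(1))

    if year is not None and YEAR_MIN <= year <= year_max:
        if report is not None:
            report.record_match("eventDate", source, verbatim, str(year))
        return year
    if report is not None:
        report.record_miss("eventDate", source, verbatim)
    return None


def default_vocabularies() -> dict[str, ControlledVocabulary]:
    """Built-in translation tables covering common source spellings.

    Users extend these through per-field translation-table files; the
    built-ins only map the unambiguous everyday variants.
    """
    make = ControlledVocabulary
    return {
        "occurrenceStatus": make(
            "occurrenceStatus",
            FIXED_VOCABULARIES["occurrenceStatus"],
            {
                normalize(v): c
                for v, c in {
                    "extant": "present",
                    "presence": "present",
                    "reported": "present",
                    "extinct": "absent",
                    "eradicated": "absent",
                    "locally extinct": "absent",
                }.items()
            },
        ),
        "establishmentMeans": make(
            "establishmentMeans",
            FIXED_VOCABULARIES["establishmentMeans"],
            {
                normalize(v): c
                for v, c in {
                    "alien": "introduced",
                    "exotic": "introduced",
                    "non-native": "introduced",
                    "introduced (alien)": "introduced",
                    "indigenous": "native",
                    "native - endemic": "native",
                    "native - non endemic": "native",
                    "endemic": "native",
                    "reintroduced": "native",
                    "vagrant (casual)": "vagrant",
                    "cryptogenic": "uncertain",
                    "unknown": "uncertain",
                }.items()
            },
        ),
        "degreeOfEstablishment": make(
            "degreeOfEstablishment",
            FIXED_VOCABULARIES["degreeOfEstablishment"],
            {
                normalize(v): c
                for v, c in {
                    "established outdoors": "established",
                    "naturalized": "established",
                    "naturalised": "established",
                    "breeding": "reproducing",
                    "reproducing in the wild": "reproducing",
                    "invasive (high impact)": "invasive",
                }.items()
            },
        ),
        "habitat": make(
            "habitat",
            FIXED_VOCABULARIES["habitat"],
            {
                normalize(v): c
                for v, c in {
                    "sea": "marine",
                    "saltwater": "marine",
                    "land": "terrestrial",
                    "limnic": "freshwater",
                    "fresh water": "freshwater",
                    "brackish water": "brackish",
                }.items()
            },
        ),
        "pathway": make(
            "pathway",
            frozenset(PATHWAY_TERMS),
            {
                normalize(v): c
                for v, c in {
                    "released": "release in nature",
                    "escape": "escape from confinement",
                    "escaped": "escape from confinement",
                    "contaminant": "transport-contaminant",
                    "stowaway": "transport-stowaway",
                    "natural dispersal": "unaided",
                }.items()
            },
        ),
    }
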