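"""Domain types, controlled vocabularies and the two output-table schemas.

The workflow produces two flat tables:

* the **record table** — one row per (taxon, location, establishment class)
  with Darwin Core invasion-status fields and source provenance;
* the **taxa table** — one row per verbatim taxon name supplied by any
  source, with the backbone-matching outcome and higher taxonomy.

Absent values are written as empty strings (never "NA") so that a
serialize/read round trip is lossless. Composite fields join their parts
with ``"; "``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from sinas._text import normalize

SEP = "; "

# Darwin Core-aligned controlled vocabularies of the status fields.
OCCURRENCE_STATUS_TERMS = frozenset({"present", "absent"})
ESTABLISHMENT_MEANS_TERMS = frozenset({"native", "introduced", "vagrant", "uncertain"})
DEGREE_OF_ESTABLISHMENT_TERMS = frozenset({"established", "reproducing", "invasive"})
HABITAT_TERMS = frozenset({"brackish", "freshwater", "marine", "terrestrial"})
# CBD top-level pathway categories; extensible through the pathway translation table.
PATHWAY_TERMS = frozenset(
    {
        "release in nature",
        "escape from confinement",
        "transport-contaminant",
        "transport-stowaway",
        "corridor",
        "unaided",
    }
)

FIXED_VOCABULARIES: dict[str, frozenset[str]] = {
    "occurrenceStatus": OCCURRENCE_STATUS_TERMS,
    "establishmentMeans": ESTABLISHMENT_MEANS_TERMS,
    "degreeOfEstablishment": DEGREE_OF_ESTABLISHMENT_TERMS,
    "habitat": HABITAT_TERMS,
}

# Composite establishment label produced when introduced and uncertain
# records for the same taxon and location are concatenated on merge.
INTRODUCED_UNCERTAIN = "introduced" + SEP + "uncertain"

RECORD_COLUMNS = [
    "location",
    "locationID",
    "taxon",
    "taxonID",
    "eventDate",
    "habitat",
    "occurrenceStatus",
    "establishmentMeans",
    "degreeOfEstablishment",
    "pathway",
    "datasetName",
    "bibliographicCitation",
]

TAXA_COLUMNS = [
    "scientificName",
    "verbatimTaxonRank",  # original name as supplied by the source (header kept as published)
    "taxon",
    "GBIFstatus",
    "GBIFstatus_Synonym",
    "GBIFmatchtype",
    "GBIFtaxonRank",
    "GBIFusageKey",
    "GBIFnote",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "taxonID",
    "taxaGroup",
]

DEFAULT_RECORDS_FILENAME = "SInAS_output.csv"
DEFAULT_TAXA_FILENAME = "SInAS_output_FullTaxaList.csv"


@dataclass
class RawRecord:
    """One source-native occurrence row after column mapping, values verbatim."""

    source_name: str
    taxon_verbatim: str
    location_verbatim: str
    establishment_verbatim: str = ""
    occurrence_verbatim: str = ""
    degree_verbatim: str = ""
    pathway_verbatim: str = ""
    habitat_verbatim: str = ""
    event_date_verbatim: str = ""
    author_hint: str = ""
    kingdom_hint: str = ""
    group_hint: str = ""


@dataclass
class ControlledVocabulary:
    """A translation table for one status field.

    ``variant_map`` maps *normalized* verbatim variants to canonical terms;
    every canonical term maps to itself so already-standard values pass
    through unchanged.
    """

    field_name: str
    canonical_terms: frozenset[str]
    variant_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term in self.canonical_terms:
            self.variant_map.setdefault(normalize(term), term)
        bad = {v for v in self.variant_map.values() if v not in self.canonical_terms}
        if bad:
            raise ValueError(
                f"{self.field_name}: variant targets outside the canonical set: {sorted(bad)}"
            )
        if self.field_name in FIXED_VOCABULARIES:
            extra = self.canonical_terms - FIXED_VOCABULARIES[self.field_name]
            if extra:
                raise ValueError(
                    f"{self.field_name}: terms outside the fixed vocabulary: {sorted(extra)}"
                )

    def lookup(self, verbatim: str) -> str | None:
        return self.variant_map.get(normalize(verbatim))


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    """Write an output table: UTF-8 CSV, header row, RFC-4180 quoting.

    Absent values become empty strings; a rerun on identical input is
    byte-identical (fixed column order, ``\\n`` line terminator).
    """
    out = df.reindex(columns=columns).fillna("")
    out = out.astype(str).replace({"<NA>": "", "nan": "", "None": ""})
    out.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` losslessly (all-string, '' = absent)."""
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def _has(value: object) -> bool:
    return value is not None and str(value) != "" and str(value) != "nan"


def validate_output_tables(records: pd.DataFrame, taxa: pd.DataFrame) -> list[str]:
    """Check both output tables against the schema contracts.

    Returns an empty list iff every invariant holds; otherwise one message
    per violating row and rule. A missing required column raises
    ``SchemaError`` naming the column.
    """
    violations: list[str] = []
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"records table is missing required column '{col}'")
    for col in TAXA_COLUMNS:
        if col not in taxa.columns:
            raise SchemaError(f"taxa table is missing required column '{col}'")

    seen_keys: dict[tuple, int] = {}
    for idx, row in records.iterrows():
        key = (str(row["taxonID"]), str(row["locationID"]), str(row["establishmentMeans"]))
        if key in seen_keys:
            violations.append(
                f"records row {idx}: duplicate (taxonID, locationID, establishmentMeans) "
                f"{key} first seen at row {seen_keys[key]}"
            )
        else:
            seen_keys[key] = idx
        em = str(row["establishmentMeans"])
        if (_has(row["degreeOfEstablishment"]) or _has(row["pathway"])) and not em.startswith(
            "introduced"
        ):
            violations.append(
                f"records row {idx}: degreeOfEstablishment/pathway set but "
                f"establishmentMeans is '{em}' (must start with 'introduced')"
            )
        if _has(em) and em != INTRODUCED_UNCERTAIN and em not in ESTABLISHMENT_MEANS_TERMS:
            violations.append(f"records row {idx}: establishmentMeans '{em}' not in vocabulary")
        if _has(row["occurrenceStatus"]) and row["occurrenceStatus"] not in OCCURRENCE_STATUS_TERMS:
            violations.append(
                f"records row {idx}: occurrenceStatus '{row['occurrenceStatus']}' not in vocabulary"
            )
        if _has(row["habitat"]):
            parts = str(row["habitat"]).split(SEP)
            bad = [p for p in parts if p not in HABITAT_TERMS]
            if bad:
                violations.append(f"records row {idx}: habitat terms {bad} not in vocabulary")
        if not _has(row["datasetName"]):
            violations.append(f"records row {idx}: datasetName is empty")

    taxa_ids = taxa["taxonID"].astype(str)
    dup_ids = taxa_ids[taxa_ids.duplicated()].unique().tolist()
    for tid in dup_ids:
        violations.append(f"taxa table: taxonID '{tid}' is not unique")
    taxa_pairs = set(zip(taxa_ids, taxa["taxon"].astype(str)))
    for idx, row in taxa.iterrows():
        if str(row["GBIFstatus"]) == "MISSING":
            for col in ("GBIFusageKey", "taxaGroup", "kingdom", "genus", "species"):
                if _has(row[col]):
                    violations.append(
                        f"taxa row {idx}: GBIFstatus MISSING but '{col}' is populated"
                    )
    for idx, row in records.iterrows():
        pair = (str(row["taxonID"]), str(row["taxon"]))
        if pair not in taxa_pairs:
            violations.append(
                f"records row {idx}: (taxonID, taxon) {pair} has no matching taxa-table row"
            )
    record_ids = set(records["taxonID"].astype(str))
    multiplicity = taxa_ids.value_counts()
    for tid in sorted(record_ids):
        if multiplicity.get(tid, 0) != 1:
            violations.append(
                f"taxonID '{tid}' used in records appears {multiplicity.get(tid, 0)} times in taxa table"
            )
    return violations


class SchemaError(ValueError):
    """A required output-table column is missing."""
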