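"""Merging of standardized records into the final two-table dataset.

Merge semantics, applied per (taxon, location):

* records with different establishment means stay separate — a species
  can legitimately be both native and introduced in one location;
* *introduced* and *uncertain* records are the exception: they are
  concatenated into a single record labelled ``"introduced; uncertain"``
  when both occur, so all alien-status evidence sits in one row;
* duplicates (same taxon, location, establishment class) collapse into
  one record; the earliest reported first-record year wins;
* degree of establishment and pathway describe the alien status only and
  attach exclusively to introduced-flagged records;
* habitat describes the taxon, not the location: values are pooled per
  taxon and written to every record of that taxon;
* provenance is the ``"; "``-joined sorted set of contributing source
  abbreviations, with citations aligned in the same order.

Records whose location could not be standardized, or which lack an
establishment value after scope inheritance, never reach the output: they
are routed to an exclusion report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from sinas.data_model import (
    DEFAULT_RECORDS_FILENAME,
    DEFAULT_TAXA_FILENAME,
    RECORD_COLUMNS,
    SEP,
    TAXA_COLUMNS,
    write_table,
)
from sinas.geo import LocationIndex

ROUNDING_MODE = "round-half-up to one decimal"

_DEGREE_PROGRESSION = ["established", "reproducing", "invasive"]


@dataclass
class StandardizedRecord:
    """One record after term, location, taxon and date standardization."""

    source_name: str
    taxon: str  # accepted (or verbatim-if-unmatched) name
    location_verbatim: str
    location_id: int | None
    location_name: str | None
    establishment: str | None  # canonical establishmentMeans
    occurrence: str | None = None
    degree: str | None = None
    pathway: str | None = None
    habitat: str = ""  # "; "-joined canonical habitats (taxon-level)
    year: int | None = None


@dataclass
class MergeResult:
    records: pd.DataFrame
    exclusions: pd.DataFrame
    conflicts: list[str] = field(default_factory=list)


_ALIEN_CLASS = {"introduced", "uncertain", "introduced" + SEP + "uncertain"}


def _establishment_label(values: set[str]) -> str:
    parts: set[str] = set()
    for v in values:
        parts.update(v.split(SEP))
    if {"introduced", "uncertain"} <= parts:
        return "introduced" + SEP + "uncertain"
    return next(iter(parts))


def merge_records(
    records: list[StandardizedRecord],
    citations: dict[str, str],
    locations: LocationIndex | None = None,
) -> MergeResult:
    """Deterministic merge of standardized records into the record table.

    Output rows are sorted by (taxon, locationID, establishmentMeans) so
    the result is independent of input record and source order.
    """
    exclusion_rows: list[dict] = []
    conflicts: list[str] = []

    valid: list[StandardizedRecord] = []
    for rec in records:
        if rec.location_id is None:
            exclusion_rows.append(
                {
                    "source": rec.source_name,
                    "field": "location",
                    "verbatim": rec.location_verbatim,
                    "reason": "unmatched location",
                }
            )
        elif not rec.establishment:
            exclusion_rows.append(
                {
                    "source": rec.source_name,
                    "field": "establishmentMeans",
                    "verbatim": rec.taxon,
                    "reason": "missing establishment after scope inheritance",
                }
            )
        else:
            valid.append(rec)

    # habitat pools per taxon across every surviving record
    taxon_habitat: dict[str, set[str]] = {}
    for rec in valid:
        if rec.habitat:
            taxon_habitat.setdefault(rec.taxon, set()).update(rec.habitat.split(SEP))

    # bucket: native and vagrant merge within themselves; introduced and
    # uncertain share one bucket and may concatenate
    groups: dict[tuple[str, int, str], list[StandardizedRecord]] = {}
    for rec in valid:
        bucket = "alien" if rec.establishment in _ALIEN_CLASS else rec.establishment
        groups.setdefault((rec.taxon, rec.location_id, bucket), []).append(rec)

    rows: list[dict] = []
    for (taxon, loc_id, _bucket), members in groups.items():
        establishment = _establishment_label({m.establishment for m in members})
        introduced_like = establishment.startswith("introduced")

        years = [m.year for m in members if m.year is not None]
        occurrences = {m.occurrence for m in members if m.occurrence}
        if occurrences == {"present", "absent"}:
            conflicts.append(
                f"occurrenceStatus conflict for taxon '{taxon}' location {loc_id} "
                f"({establishment}): present kept over absent"
            )
        occurrence = "present" if "present" in occurrences else ("absent" if occurrences else "")

        degrees = {m.degree for m in members if m.degree} if introduced_like else set()
        degree = ""
        if degrees:  # furthest progression wins when sources disagree
            degree = max(degrees, key=_DEGREE_PROGRESSION.index)
        pathways = (
            sorted({p for m in members for p in (m.pathway or "").split(SEP) if p})
            if introduced_like
            else []
        )

        sources = sorted({m.source_name for m in members})
        loc_name = members[0].location_name
        if loc_name is None and locations is not None:
            loc_name = locations.by_id[loc_id].name
        rows.append(
            {
                "location": loc_name or "",
                "locationID": loc_id,
                "taxon": taxon,
                "eventDate": "" if not years else min(years),
                "habitat": SEP.join(sorted(taxon_habitat.get(taxon, set()))),
                "occurrenceStatus": occurrence,
                "establishmentMeans": establishment,
                "degreeOfEstablishment": degree,
                "pathway": SEP.join(pathways),
                "datasetName": SEP.join(sources),
                "bibliographicCitation": SEP.join(citations.get(s, "") for s in sources),
            }
        )

    records_df = pd.DataFrame(
        rows, columns=[c for c in RECORD_COLUMNS if c != "taxonID"]
    ).sort_values(["taxon", "locationID", "establishmentMeans"], kind="mergesort")
    records_df = records_df.reset_index(drop=True)

    excl = (
        pd.DataFrame(exclusion_rows, columns=["source", "field", "verbatim", "reason"])
        .groupby(["source", "field", "verbatim", "reason"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["source", "field", "verbatim"], kind="mergesort")
        .reset_index(drop=True)
    )
    return MergeResult(records=records_df, exclusions=excl, conflicts=conflicts)


def assign_ids(
    records: pd.DataFrame, taxa: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign stable taxon identifiers; location identifiers come from the
    translation table and are already on the records.

    taxonIDs are consecutive positive integers over taxa rows sorted
    lexicographically by (taxon, verbatim name) — identical input yields
    identical IDs, and appending a lexicographically-last taxon leaves all
    existing IDs unchanged. A record carries the ID of the first taxa row
    sharing its accepted taxon, so every (taxonID, taxon) pair on a record
    exists in the taxa table.
    """
    taxa = taxa.sort_values(["taxon", "verbatimTaxonRank"], kind="mergesort").reset_index(
        drop=True
    )
    taxa = taxa.copy()
    taxa["taxonID"] = range(1, len(taxa) + 1)
    first_id = taxa.groupby("taxon", sort=False)["taxonID"].min()

    records = records.copy()
    if len(records):
        records["taxonID"] = records["taxon"].map(first_id).astype(int)
    else:
        records["taxonID"] = pd.Series(dtype=int)
    records = records.reindex(columns=RECORD_COLUMNS)
    taxa = taxa.reindex(columns=TAXA_COLUMNS)
    return records, taxa


def percentage(count: int, denominator: int) -> float | None:
    """Share of ``count`` in ``denominator`` as a percentage, one decimal,
    round-half-up; ``None`` when the denominator is zero."""
    if denominator == 0:
        return None
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class DatasetSummary:
    n_records: int
    n_taxa_total: int
    n_taxa_alien_distribution: int
    n_taxa_native_distribution: int
    n_locations: int
    establishment_counts: dict[str, int]
    establishment_pct: dict[str, float]
    coverage_counts: dict[str, int]
    coverage_pct: dict[str, float]
    n_taxa_with_habitat: int
    pct_taxa_with_habitat: float | None
    n_taxa_matched_backbone: int
    pct_taxa_matched_backbone: float | None
    taxa_group_counts: dict[str, int]
    rounding_mode: str = ROUNDING_MODE


def summarize_dataset(records: pd.DataFrame, taxa: pd.DataFrame) -> DatasetSummary:
    """Exact group-by counts over the two output tables.

    Record-level percentages use the record count as denominator;
    taxon-level percentages use the taxa-table row count. Percentages are
    absent (None) for an empty dataset.
    """
    n_records = len(records)
    n_taxa = len(taxa)

    em = records["establishmentMeans"].astype(str) if n_records else pd.Series(dtype=str)
    est_counts = em.value_counts().to_dict()
    est_pct = {k: percentage(v, n_records) for k, v in est_counts.items()}

    def _nonempty(col: str) -> int:
        if not n_records:
            return 0
        return int((records[col].astype(str).str.len() > 0).sum())

    coverage = {
        col: _nonempty(col)
        for col in ("degreeOfEstablishment", "occurrenceStatus", "pathway", "eventDate")
    }
    coverage_pct = {k: percentage(v, n_records) for k, v in coverage.items()}

    alien_mask = em.str.startswith("introduced") | em.isin(["uncertain", "vagrant"])
    native_mask = em == "native"
    n_alien_taxa = records.loc[alien_mask, "taxon"].nunique() if n_records else 0
    n_native_taxa = records.loc[native_mask, "taxon"].nunique() if n_records else 0

    taxa_habitat = 0
    if n_records:
        taxa_habitat = (
            records.loc[records["habitat"].astype(str).str.len() > 0, "taxon"].nunique()
        )
    matched = (
        int((taxa["GBIFstatus"].astype(str) != "MISSING").sum()) if n_taxa else 0
    )
    groups = (
        taxa.loc[taxa["taxaGroup"].astype(str).str.len() > 0, "taxaGroup"]
        .value_counts()
        .to_dict()
        if n_taxa
        else {}
    )
    return DatasetSummary(
        n_records=n_records,
        n_taxa_total=n_taxa,
        n_taxa_alien_distribution=int(n_alien_taxa),
        n_taxa_native_distribution=int(n_native_taxa),
        n_locations=records["locationID"].nunique() if n_records else 0,
        establishment_counts=est_counts,
        establishment_pct=est_pct,
        coverage_counts=coverage,
        coverage_pct=coverage_pct,
        n_taxa_with_habitat=int(taxa_habitat),
        pct_taxa_with_habitat=percentage(int(taxa_habitat), records["taxon"].nunique() if n_records else 0),
        n_taxa_matched_backbone=matched,
        pct_taxa_matched_backbone=percentage(matched, n_taxa),
        taxa_group_counts=groups,
    )


def write_outputs(
    records: pd.DataFrame,
    taxa: pd.DataFrame,
    reports: dict[str, pd.DataFrame],
    destination: str | Path,
    records_filename: str = DEFAULT_RECORDS_FILENAME,
    taxa_filename: str = DEFAULT_TAXA_FILENAME,
) -> dict[str, Path]:
    """Write the two main tables plus the report files.

    ``reports`` maps report names (e.g. ``unmatched_terms``,
    ``unmatched_locations``, ``exclusions``) to frames. Main tables are
    written last-after-validation by the pipeline; reruns on identical
    input are byte-identical because every table is fully sorted upstream
    and written with a fixed dialect.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    if not dest.is_dir():
        raise IOError(f"destination '{dest}' is not a writable directory")
    written: dict[str, Path] = {}
    for name, frame in sorted(reports.items()):
        path = dest / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
        written[name] = path
    records_path = dest / records_filename
    taxa_path = dest / taxa_filename
    write_table(records, records_path, RECORD_COLUMNS)
    write_table(taxa, taxa_path, TAXA_COLUMNS)
    written["records"] = records_path
    written["taxa"] = taxa_path
    return written
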