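"""Per-source ingestion through declarative configurations.

Every source dataset is described by a :class:`SourceConfig` — data, not
code: a column map from workflow roles (taxon, location, establishment,
...) to source-native column names, inclusion/exclusion rules on raw
values, an optional binary establishment encoding, an ordered list of
location columns (finest first) for sources that scatter locations across
columns, and the citation strings echoed verbatim into the output. New
sources are added by writing a config block, never by changing code.

Sources with scope ``alien`` or ``native`` need no establishment column:
every record inherits the scope ("introduced" / "native"). Mixed-scope
sources must carry establishment information per record. Rows failing a
filter are counted per (source, rule) and reported.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from sinas._text import normalize
from sinas.data_model import RawRecord

ROLE_ATTRS = {
    "taxon": "taxon_verbatim",
    "location": "location_verbatim",
    "establishment": "establishment_verbatim",
    "occurrence": "occurrence_verbatim",
    "degree": "degree_verbatim",
    "pathway": "pathway_verbatim",
    "habitat": "habitat_verbatim",
    "event_date": "event_date_verbatim",
    "author": "author_hint",
    "kingdom": "kingdom_hint",
    "group": "group_hint",
}

SCOPE_ESTABLISHMENT = {"alien": "introduced", "native": "native"}


class SourceConfigError(ValueError):
    pass


@dataclass
class FilterRule:
    column: str  # a role name or a raw-file column name
    values: list[str]

    def matches(self, value: str) -> bool:
        norm = normalize(value)
        return any(norm == normalize(v) for v in self.values)


@dataclass
class IngestLog:
    """Per-(source, reason) drop counters plus unknown-code tallies."""

    drops: Counter = field(default_factory=Counter)
    unknown_codes: Counter = field(default_factory=Counter)

    def drop(self, source: str, reason: str, n: int = 1) -> None:
        self.drops[(source, reason)] += n

    def unknown_code(self, source: str, code: str) -> None:
        self.unknown_codes[(source, code)] += 1


@dataclass
class SourceConfig:
    source_name: str
    citation: str
    scope: str  # alien | native | mixed
    column_map: dict[str, str] = field(default_factory=dict)
    keep_rules: list[FilterRule] = field(default_factory=list)
    drop_rules: list[FilterRule] = field(default_factory=list)
    establishment_encoding: dict[str, str] = field(default_factory=dict)
    location_columns_priority: list[str] = field(default_factory=list)
    restrict_to_list: list[str] | None = None  # normalized-name registry restriction
    kind: str = "checklist"  # checklist | range_map
    origin_keep: list[str] = field(default_factory=list)  # range-map origin codes to keep
    habitat_delimiter: str = ";"
    delimiter: str = ","
    encoding: str = "utf-8"

    def __post_init__(self) -> None:
        if self.scope not in ("alien", "native", "mixed"):
            raise SourceConfigError(f"{self.source_name}: invalid scope '{self.scope}'")
        if self.kind not in ("checklist", "range_map"):
            raise SourceConfigError(f"{self.source_name}: invalid kind '{self.kind}'")

    @classmethod
    def from_dict(cls, data: dict) -> "SourceConfig":
        rules = lambda key: [FilterRule(r["column"], list(r["values"])) for r in data.get(key, [])]
        restrict = data.get("restrict_to_list")
        if isinstance(restrict, str):  # companion name-list file, one name per line
            restrict = [
                line.strip()
                for line in Path(restrict).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
        return cls(
            source_name=data["source_name"],
            citation=data.get("citation", ""),
            scope=data.get("scope", "mixed"),
            column_map=dict(data.get("column_map", {})),
            keep_rules=rules("keep_rules"),
            drop_rules=rules("drop_rules"),
            establishment_encoding={
                str(k): str(v) for k, v in data.get("establishment_encoding", {}).items()
            },
            location_columns_priority=list(data.get("location_columns_priority", [])),
            restrict_to_list=restrict,
            kind=data.get("kind", "checklist"),
            origin_keep=list(data.get("origin_keep", [])),
            habitat_delimiter=data.get("habitat_delimiter", ";"),
            delimiter=data.get("delimiter", ","),
            encoding=data.get("encoding", "utf-8"),
        )


def combine_location_columns(
    row: dict[str, str], config: SourceConfig
) -> str | None:
    """First non-empty location cell in priority order (finest first);
    ``None`` when every cell is empty (the record is then dropped)."""
    for col in config.location_columns_priority:
        if col not in row:
            raise SourceConfigError(
                f"{config.source_name}: location column '{col}' missing from file"
            )
        if str(row[col]).strip():
            return str(row[col]).strip()
    return None


def decode_establishment(record: RawRecord, config: SourceConfig, log: IngestLog | None = None) -> RawRecord:
    """Translate binary/coded establishment values (e.g. 0 -> introduced).

    Unknown codes are left verbatim and logged once per occurrence.
    """
    if not config.establishment_encoding:
        raise SourceConfigError(f"{config.source_name}: no establishment_encoding configured")
    raw = record.establishment_verbatim.strip()
    if raw in config.establishment_encoding:
        return replace(record, establishment_verbatim=config.establishment_encoding[raw])
    if raw and log is not None:
        log.unknown_code(config.source_name, raw)
    return record


def load_source(
    path: str | Path, config: SourceConfig, log: IngestLog | None = None
) -> list[RawRecord]:
    """Read one checklist source into RawRecords, verbatim values preserved.

    Raw-column filter rules (rules naming columns that are not workflow
    roles) are applied on the raw rows here, so that source-specific
    inclusion criteria can reference columns that never enter the mapped
    record. Rows with an empty taxon or location are dropped and counted.
    """
    log = log if log is not None else IngestLog()
    with open(path, newline="", encoding=config.encoding) as fh:
        reader = csv.DictReader(fh, delimiter=config.delimiter)
        header = reader.fieldnames or []
        for role, col in config.column_map.items():
            if role == "location" and config.location_columns_priority:
                continue
            if col not in header:
                raise SourceConfigError(
                    f"{config.source_name}: mapped column '{col}' (role {role}) "
                    f"missing from {path}"
                )
        for col in config.location_columns_priority:
            if col not in header:
                raise SourceConfigError(
                    f"{config.source_name}: location column '{col}' missing from {path}"
                )

        role_set = set(ROLE_ATTRS)
        raw_keep = [r for r in config.keep_rules if r.column not in role_set]
        raw_drop = [r for r in config.drop_rules if r.column not in role_set]
        for rule in raw_keep + raw_drop:
            if rule.column not in header:
                raise SourceConfigError(
                    f"{config.source_name}: filter column '{rule.column}' missing from {path}"
                )

        records: list[RawRecord] = []
        for row in reader:
            if any(not rule.matches(row.get(rule.column, "")) for rule in raw_keep):
                log.drop(config.source_name, "keep_rule")
                continue
            if any(rule.matches(row.get(rule.column, "")) for rule in raw_drop):
                log.drop(config.source_name, "drop_rule")
                continue

            values = {"source_name": config.source_name}
            for role, attr in ROLE_ATTRS.items():
                col = config.column_map.get(role)
                values[attr] = str(row.get(col, "") or "").strip() if col else ""
            if config.location_columns_priority:
                combined = combine_location_columns(row, config)
                if combined is None:
                    log.drop(config.source_name, "empty_location")
                    continue
                values["location_verbatim"] = combined

            record = RawRecord(**values)
            if not record.taxon_verbatim:
                log.drop(config.source_name, "empty_taxon")
                continue
            if not record.location_verbatim:
                log.drop(config.source_name, "empty_location")
                continue
            if config.establishment_encoding:
                record = decode_establishment(record, config, log)
            if not record.establishment_verbatim and config.scope in SCOPE_ESTABLISHMENT:
                record = replace(
                    record, establishment_verbatim=SCOPE_ESTABLISHMENT[config.scope]
                )
            records.append(record)
    return records


def apply_source_filters(
    records: list[RawRecord], config: SourceConfig, log: IngestLog | None = None
) -> list[RawRecord]:
    """Apply role-based keep/drop rules and the optional registry restriction.

    Returns exactly the records satisfying all keep rules and no drop
    rule, in their original order. Idempotent; an empty result is legal.
    """
    log = log if log is not None else IngestLog()
    role_set = set(ROLE_ATTRS)
    keep = [r for r in config.keep_rules if r.column in role_set]
    drop = [r for r in config.drop_rules if r.column in role_set]
    restrict = (
        {normalize(name) for name in config.restrict_to_list}
        if config.restrict_to_list is not None
        else None
    )

    out: list[RawRecord] = []
    for rec in records:
        if any(not rule.matches(getattr(rec, ROLE_ATTRS[rule.column])) for rule in keep):
            log.drop(rec.source_name, "keep_rule")
            continue
        if any(rule.matches(getattr(rec, ROLE_ATTRS[rule.column])) for rule in drop):
            log.drop(rec.source_name, "drop_rule")
            continue
        if restrict is not None and normalize(rec.taxon_verbatim) not in restrict:
            log.drop(rec.source_name, "not_on_registry")
            continue
        out.append(rec)
    return out
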