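"""End-to-end orchestration: one configuration file drives a full run.

Stages: ingest -> term/location/taxon/date standardization -> merge ->
validate -> write. Every stage feeds the run manifest (config hash,
record counts, timings); record-level decisions (exclusions, unmatched
terms, homonym flags) go to the report files, not the log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from sinas.data_model import RawRecord, validate_output_tables
from sinas.geo import (
    LocationIndex,
    Unmatched,
    load_locations,
    load_range_features,
    overlay_range_maps,
    standardize_location,
)
from sinas.integrator import (
    MergeResult,
    StandardizedRecord,
    assign_ids,
    merge_records,
    summarize_dataset,
    write_outputs,
)
from sinas.source_ingest import IngestLog, SourceConfig, apply_source_filters, load_source
from sinas.taxon_matcher import (
    GbifServiceBackbone,
    LocalBackbone,
    TaxonMatch,
    build_taxa_list,
    match_taxon,
)
from sinas.term_standardizer import (
    TermMatchReport,
    default_vocabularies,
    load_vocabulary,
    standardize_event_date,
    standardize_habitat,
    standardize_term,
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    sources: list[dict]  # each: SourceConfig fields plus 'path'
    location_polygons: str
    location_translation: str
    backbone_mode: str = "fixture"  # fixture | live-cached
    backbone_path: str | None = None
    output_dir: str = "output"
    vocabulary_paths: dict[str, str] = field(default_factory=dict)
    taxon_matching: bool = True
    min_area_fraction: float = 0.0
    records_filename: str = "SInAS_output.csv"
    taxa_filename: str = "SInAS_output_FullTaxaList.csv"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        base = Path(path).parent

        def _resolve(p: str | None) -> str | None:
            return None if p is None else str((base / p) if not Path(p).is_absolute() else p)

        sources = []
        for src in data.get("sources", []):
            src = dict(src)
            src["path"] = _resolve(src["path"])
            if isinstance(src.get("restrict_to_list"), str):
                src["restrict_to_list"] = _resolve(src["restrict_to_list"])
            sources.append(src)
        backbone = data.get("backbone", {})
        return cls(
            sources=sources,
            location_polygons=_resolve(data["locations"]["polygons"]),
            location_translation=_resolve(data["locations"]["translation"]),
            backbone_mode=backbone.get("mode", "fixture"),
            backbone_path=_resolve(backbone.get("path")),
            output_dir=_resolve(data.get("output_dir", "output")),
            vocabulary_paths={
                k: _resolve(v) for k, v in data.get("vocabularies", {}).items()
            },
            taxon_matching=data.get("stages", {}).get("taxon_matching", True),
            min_area_fraction=data.get("options", {}).get("min_area_fraction", 0.0),
            records_filename=data.get("options", {}).get(
                "records_filename", "SInAS_output.csv"
            ),
            taxa_filename=data.get("options", {}).get(
                "taxa_filename", "SInAS_output_FullTaxaList.csv"
            ),
        )

    def validate(self) -> list[str]:
        problems = []
        if self.backbone_mode not in ("fixture", "live-cached"):
            problems.append(f"invalid backbone mode '{self.backbone_mode}'")
        if self.taxon_matching and not self.backbone_path:
            problems.append("taxon matching enabled but no backbone path configured")
        for label, p in [
            ("location polygons", self.location_polygons),
            ("location translation table", self.location_translation),
        ]:
            if not Path(p).exists():
                problems.append(f"{label} not found: {p}")
        if self.taxon_matching and self.backbone_path and not Path(self.backbone_path).exists():
            problems.append(f"backbone file not found: {self.backbone_path}")
        for src in self.sources:
            if not Path(src["path"]).exists():
                problems.append(f"source file not found: {src['path']}")
        for fieldname, p in self.vocabulary_paths.items():
            if not Path(p).exists():
                problems.append(f"translation table for {fieldname} not found: {p}")
        return problems

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: pd.DataFrame
    taxa: pd.DataFrame
    reports: dict[str, pd.DataFrame]
    summary: object
    manifest: dict
    written: dict[str, Path]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def _load_vocabularies(config: RunConfig):
    vocabs = default_vocabularies()
    for fieldname, path in config.vocabulary_paths.items():
        vocabs[fieldname] = load_vocabulary(path, fieldname)
    return vocabs


def ingest_all(config: RunConfig, locations: LocationIndex, log: IngestLog) -> list[RawRecord]:
    """Run every configured source through its declarative preparation."""
    raw: list[RawRecord] = []
    for src in config.sources:
        src_cfg = SourceConfig.from_dict({k: v for k, v in src.items() if k != "path"})
        if src_cfg.kind == "range_map":
            features = load_range_features(src["path"], src_cfg.source_name)
            records = overlay_range_maps(
                features,
                locations,
                origin_keep=set(src_cfg.origin_keep),
                min_area_fraction=config.min_area_fraction,
            )
            records = apply_source_filters(records, src_cfg, log)
        else:
            records = load_source(src["path"], src_cfg, log)
            records = apply_source_filters(records, src_cfg, log)
        raw.extend(records)
    return raw


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute a full harmonization run.

    Returns the in-memory tables, reports and manifest; with ``write=True``
    the outputs are written only after schema validation passes.
    """
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))

    manifest: dict = {"config_hash": config.config_hash(), "stages": {}, "timings_s": {}}
    t0 = time.perf_counter()

    locations = load_locations(config.location_polygons, config.location_translation)
    vocabs = _load_vocabularies(config)
    backbone = None
    if config.taxon_matching:
        if config.backbone_mode == "fixture":
            backbone = LocalBackbone.from_file(config.backbone_path)
        else:
            backbone = GbifServiceBackbone(config.backbone_path)
    manifest["timings_s"]["load_reference"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    ingest_log = IngestLog()
    raw_records = ingest_all(config, locations, ingest_log)
    manifest["stages"]["ingested_records"] = len(raw_records)
    manifest["timings_s"]["ingest"] = round(time.perf_counter() - t1, 3)

    t2 = time.perf_counter()
    term_report = TermMatchReport()
    unmatched_locations: dict[tuple[str, str], int] = {}
    match_cache: dict[tuple, TaxonMatch] = {}
    matches: list[TaxonMatch] = []
    standardized: list[StandardizedRecord] = []
    citations: dict[str, str] = {
        src["source_name"]: src.get("citation", "") for src in config.sources
    }

    for rec in raw_records:
        loc = standardize_location(rec.location_verbatim, locations)
        if isinstance(loc, Unmatched):
            key = (rec.source_name, rec.location_verbatim)
            unmatched_locations[key] = unmatched_locations.get(key, 0) + 1
            loc_id, loc_name = None, None
        else:
            loc_id, loc_name = loc.location_id, loc.name

        hints = {
            "author": rec.author_hint,
            "kingdom": rec.kingdom_hint,
            "group": rec.group_hint,
        }
        cache_key = (rec.taxon_verbatim, rec.author_hint, rec.kingdom_hint, rec.group_hint)
        if cache_key not in match_cache:
            if backbone is None:
                match_cache[cache_key] = TaxonMatch(
                    verbatim_name=rec.taxon_verbatim, taxon=rec.taxon_verbatim, status="MISSING"
                )
            else:
                match_cache[cache_key] = match_taxon(rec.taxon_verbatim, backbone, hints)
        match = match_cache[cache_key]
        matches.append(match)

        establishment = standardize_term(
            "establishmentMeans",
            rec.establishment_verbatim,
            vocabs["establishmentMeans"],
            term_report,
            rec.source_name,
        )
        occurrence = standardize_term(
            "occurrenceStatus",
            rec.occurrence_verbatim,
            vocabs["occurrenceStatus"],
            term_report,
            rec.source_name,
        )
        degree = standardize_term(
            "degreeOfEstablishment",
            rec.degree_verbatim,
            vocabs["degreeOfEstablishment"],
            term_report,
            rec.source_name,
        )
        pathway = standardize_term(
            "pathway", rec.pathway_verbatim, vocabs["pathway"], term_report, rec.source_name
        )
        habitat = standardize_habitat(
            rec.habitat_verbatim, vocabs["habitat"], term_report, rec.source_name
        )
        year = standardize_event_date(rec.event_date_verbatim, term_report, rec.source_name)

        standardized.append(
            StandardizedRecord(
                source_name=rec.source_name,
                taxon=match.taxon,
                location_verbatim=rec.location_verbatim,
                location_id=loc_id,
                location_name=loc_name,
                establishment=establishment,
                occurrence=occurrence,
                degree=degree,
                pathway=pathway,
                habitat=habitat,
                year=year,
            )
        )
    manifest["stages"]["standardized_records"] = len(standardized)
    manifest["timings_s"]["standardize"] = round(time.perf_counter() - t2, 3)

    t3 = time.perf_counter()
    merged: MergeResult = merge_records(standardized, citations, locations)
    taxa = build_taxa_list(matches)
    records, taxa = assign_ids(merged.records, taxa)
    manifest["stages"]["merged_records"] = len(records)
    manifest["stages"]["taxa"] = len(taxa)
    manifest["stages"]["excluded_records"] = int(merged.exclusions["count"].sum()) if len(merged.exclusions) else 0
    manifest["timings_s"]["merge"] = round(time.perf_counter() - t3, 3)

    unmatched_loc_df = pd.DataFrame(
        [
            {"source": s, "field": "location", "verbatim": v, "count": n}
            for (s, v), n in sorted(unmatched_locations.items())
        ],
        columns=["source", "field", "verbatim", "count"],
    )
    ingest_df = pd.DataFrame(
        [
            {"source": s, "reason": r, "count": n}
            for (s, r), n in sorted(ingest_log.drops.items())
        ],
        columns=["source", "reason", "count"],
    )
    reports = {
        "unmatched_terms": term_report.unmatched_frame(),
        "matched_terms": term_report.matched_frame(),
        "unmatched_locations": unmatched_loc_df,
        "exclusions": merged.exclusions,
        "ingest_drops": ingest_df,
        "merge_conflicts": pd.DataFrame({"message": merged.conflicts}),
    }

    violations = validate_output_tables(records, taxa)
    summary = summarize_dataset(records, taxa)
    written: dict[str, Path] = {}
    if write and not violations:
        written = write_outputs(
            records,
            taxa,
            reports,
            config.output_dir,
            records_filename=config.records_filename,
            taxa_filename=config.taxa_filename,
        )
        manifest_out = dict(manifest)
        with open(Path(config.output_dir) / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest_out, fh, indent=1, sort_keys=True)

    return PipelineResult(
        records=records,
        taxa=taxa,
        reports=reports,
        summary=summary,
        manifest=manifest,
        written=written,
        violations=violations,
    )
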