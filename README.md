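# sinas

Harmonization and integration of alien-species distribution data.

Knowing both where an alien species has been introduced and where it is
native is fundamental for invasion biogeography — tracing species flows,
spotting emerging invaders, prioritizing pathways of spread. The raw
evidence, however, is scattered across heterogeneous sources: regional
checklists with source-specific column layouts and status vocabularies,
registries with binary establishment flags, and expert range maps shipped
as polygon layers. `sinas` turns that heterogeneity into a single
standardized two-table dataset:

* a **record table** — one row per taxon × location × establishment class,
  with Darwin Core invasion-status fields (`occurrenceStatus`,
  `establishmentMeans`, `degreeOfEstablishment`, `pathway`), first-record
  year, habitat, and full source provenance;
* a **taxa table** — one row per verbatim name any source supplied, with
  the backbone-matching outcome (status, match type, usage key), higher
  taxonomy and a coarse taxonomic group.

The workflow is aimed at biodiversity-informatics practitioners who need
reproducible, transparent integration: every term translation, every
dropped row and every unmatched name is counted and exported, never
silently discarded.

## What the pipeline does

1. **Ingest** — each source is described by a declarative config (column
   map, scope, inclusion rules, citation). Binary establishment codes are
   decoded, multi-column locations collapsed to the finest level, and
   sources with a fixed scope (purely alien or purely native) inherit
   their establishment value. Range-map sources are converted to
   checklists by overlaying polygons on the location layer; only
   positive-area intersections count — boundary contact is never a
   presence.
2. **Standardize** — status and habitat terms go through user-editable
   translation tables; verbatim location names resolve against a location
   reference (names, alternative spellings, subdivision up-scaling);
   first-record dates reduce to a single year (ranges take the mean,
   truncated toward the earlier year). Taxon names resolve against a
   taxonomy backbone through an exact → synonym → fuzzy cascade:
   synonyms are replaced by their accepted names and flagged, homonyms
   are arbitrated by author/kingdom/group hints (and abstain when
   unresolvable), and fuzzy matches are accepted only for a sole
   candidate at full confidence (100).
3. **Merge** — records group by (taxon, location, establishment class):
   duplicates collapse keeping the earliest year, *introduced* and
   *uncertain* evidence concatenates to `"introduced; uncertain"`,
   native/vagrant records stay separate, and provenance becomes the
   sorted, `"; "`-joined list of contributing sources.

## Worked example

The package ships a seeded fixture generator that fabricates a complete
input set — backbone, location grid, five sources in different dialects —
together with a ledger of the exact expected output:

```sh
sinas make-fixtures demo --seed 42
sinas run demo/run_config.yaml
```

which prints:

```
records: 57
taxa: 51
locations: 9
taxa with alien distribution: 35; with native distribution: 15
percentages: round-half-up to one decimal; denominators: records for record-level fields, taxa for taxon-level fields
  establishmentMeans=introduced: 38 (66.7%)
  establishmentMeans=introduced; uncertain: 1 (1.8%)
  establishmentMeans=native: 17 (29.8%)
  establishmentMeans=vagrant: 1 (1.8%)
  degreeOfEstablishment filled: 20 (35.1%)
  eventDate filled: 21 (36.8%)
  occurrenceStatus filled: 18 (31.6%)
  pathway filled: 1 (1.8%)
taxa matched against backbone: 48 (94.1%)
outputs written to demo/output
```

The 57 records are the merged taxon × location × establishment rows; the
one `introduced; uncertain` record is the planted pair of conflicting
alien-status reports concatenated on merge; 48 of 51 names matched the
fixture backbone (the three misses are a planted unresolvable homonym and
two names absent from the backbone, kept under their verbatim spelling).
`demo/output/` holds the two main CSV tables plus the report files
(unmatched terms, unmatched locations, exclusions, ingest drops).

Library use mirrors the CLI:

```python
from sinas import RunConfig, run_pipeline
result = run_pipeline(RunConfig.from_file("demo/run_config.yaml"))
result.records        # pandas DataFrame, record table
result.summary        # dataset summary with counts and percentages
```

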