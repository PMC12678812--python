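# Methods

This note documents the models, rules and numerical choices behind the
harmonization workflow, the behaviour of the synthetic fixture generator,
and the known limitations.

## The harmonization model

The workflow treats an occurrence dataset as a bag of assertions
"taxon T has establishment status E in location L (with optional status
details, a first-record year and a habitat)". Harmonization maps every
assertion into three controlled reference systems — a status vocabulary, a
location reference, a taxonomy backbone — and then merges assertions that
describe the same fact.

### Status vocabulary

Status fields follow Darwin Core terms: `occurrenceStatus`
{present, absent}, `establishmentMeans` {native, introduced, vagrant,
uncertain}, `degreeOfEstablishment` {established, reproducing, invasive},
habitat {brackish, freshwater, marine, terrestrial}, and CBD top-level
pathway categories. Translation tables (canonical term + variants) are
the single authority for mapping verbatim spellings; normalization before
lookup is deliberately minimal (Unicode NFKD, diacritics stripped,
case-fold, whitespace collapse) so that anything semantically ambiguous
must be an explicit table entry. An unmatched term never drops a record —
the field stays empty and the verbatim value goes to the per-field
unmatched report — with one exception: a record with no usable
`establishmentMeans` cannot be classified at all and is routed to the
exclusion report.

### Location reference

Locations are defined by a polygon layer (GeoJSON, WGS84) joined to a
translation table carrying the stable `locationID`, alternative names,
subdivision names (which up-scale to the parent location) and one column
per aggregation scheme. Geometries must be pairwise interior-disjoint; a
configurable equal-area overlap tolerance (default 1e-6 km², effectively
shared-vertex noise) guards the invariant at load time. Name matching
tries standardized names and alternatives before subdivisions, so a
string that is both a location name and another location's subdivision
resolves to the name; a collision within one tier raises a configuration
error when queried.

Range maps convert to checklists by polygon overlay. The intersection
predicate is positive-area overlap: boundary contact alone never yields a
presence, which avoids spurious records from shared borders. Because
coarse range maps overhang borders, an optional minimum covered-area
fraction (intersection area / location area, computed on a Lambert
cylindrical equal-area projection; default 0) can suppress slivers.
Membership tests themselves run directly in geographic coordinates —
intersect/positive-area decisions are invariant under the projection.

### Taxonomy backbone

Name resolution is a cascade with strict priority: exact match, then
synonym resolution, then fuzzy matching. Design choices:

* **Synonyms** are replaced by the accepted name of the entry they point
  to and flagged (`GBIFstatus` SYNONYM, note "Accepted name found on
  GBIF"); the accepted entry's own status (ACCEPTED or DOUBTFUL) is
  recorded in `GBIFstatus_Synonym` and never filtered on.
* **Homonyms** (several same-named candidates) are arbitrated by source
  hints in the order author → kingdom → taxonomic group; a hint only
  narrows, never empties, the candidate set. With zero or several
  survivors the match abstains — it is recorded like an unmatched name
  (no usage key, no taxonomy) with note "Homonym in GBIF" — because
  silently choosing a wrong taxon is worse than abstaining. A resolved
  homonym keeps the same note as a flag.
* **Fuzzy matches** are accepted only for a sole candidate at confidence
  100. The local table backbone defines this deterministically: 100 iff
  the query has a unique candidate within Damerau–Levenshtein distance 1
  and no other candidate within distance 2; otherwise confidence decays
  and can never reach 100. This reproduces the "high confidence only"
  behaviour of live backbone services without a network dependency.
* Unmatched names stay in the dataset under their verbatim spelling
  (`GBIFstatus` MISSING, empty taxonomy), so no occurrence information is
  lost to taxonomy gaps.

Taxa groups (Birds, Vascular plants, Insects, SAR, ...) come from an
ordered, user-editable rule table over the retrieved higher taxonomy;
first matching (rank, value) rule wins. Several groups are ecological
rather than monophyletic conveniences (Algae, Fishes, "Other aquatic
animals"); the shipped rules place class-level matches before phylum- and
kingdom-level fallbacks so the specific label always wins.

### Dates

First-record dates reduce to a single year through an explicit grammar:
4-digit year; `YYYY-YYYY`/`YYYY–YYYY` ranges (arithmetic mean, half-years
truncated toward the earlier year, consistent with the downstream
earliest-record preference); ISO dates truncated to the year; `c.`/`ca.`
prefixes stripped; `YYYYs` decades mapped to their first year. Everything
else is reported unparseable. Plausibility bounds (1000 ≤ year ≤ current
year by default) route implausible values to the report rather than the
output. The grammar is a documented stand-in for the looser conventions
found in real first-record compilations; it is intentionally strict —
silent guessing is worse than a reported miss.

### Merge semantics

Records group by (accepted taxon, locationID, establishment class) where
the classes are native, vagrant, and a single alien class covering
introduced and uncertain. Within a group: the earliest year wins;
`present` beats `absent` on conflict (a single extant report should not
be erased by an older extirpation claim) and the conflict is logged;
degree of establishment keeps the furthest progression on the
established < reproducing < invasive scale; pathways join as the sorted
unique `"; "` list. Introduced and uncertain evidence concatenates to
`"introduced; uncertain"` only when both occur; an uncertain-only group
stays `uncertain`. Degree and pathway attach exclusively to
introduced-flagged records. Habitat describes the taxon, not the
location: values pool per taxon and are written to every record of that
taxon. The merge is order-invariant (provenance lists are sorted) and
idempotent — feeding the output back through the merge reproduces it.

Identifiers: `locationID` comes from the translation table and is
authoritative; `taxonID`s are consecutive integers over taxa-table rows
sorted by (taxon, verbatim name), so reruns are stable and appending a
lexicographically-last name never renumbers existing taxa. A record
carries the ID of the first taxa row sharing its accepted taxon, keeping
the (taxonID, taxon) pairing consistent across both tables while every
verbatim name keeps its own row.

Summary percentages are round-half-up to one decimal, with record counts
as denominator for record-level fields and taxa counts for taxon-level
fields; the rounding mode is stated in every summary.

## The fixture generator

Fixtures exist to exercise code paths, not to imitate ecology. The
default set (one seed drives everything) builds a 60-name backbone with
15% synonyms, 5% homonym pairs across kingdoms and 10% planted
misspellings; a 3×3 grid of unit-square locations with alternative
spellings, subdivisions and two aggregation schemes; and five sources in
distinct dialects: a plain alien checklist, a binary-coded mixed-scope
registry (with an unknown code), a multi-column-location source, a
polygon range-map source (including a boundary-touch feature), and a
mixed-scope list with free-text status variants, homonyms and unmatched
names. Every merge rule is planted at least once (introduced+uncertain
pair, native+introduced pair, duplicates with conflicting years, an
occurrence-status conflict, an unmatched location and unmatched terms).

The generator computes its ground-truth ledger from the planting plan
with plain dictionary arithmetic, independent of the pipeline; the
end-to-end test asserts exact recovery of records, taxa and every
unmatched report. Misspellings are constructed so the distance-1
candidate is provably unique within distance 2, making fuzzy acceptance
deterministic. Synthetic binomials are pronounceable but never real
names, so a misconfigured live-backbone run cannot accidentally match.

What passing these tests does **not** show: robustness to real-world
messiness beyond the planted dialects (multi-encoding files, deeply
inconsistent date strings, backbone drift between runs), performance at
the scale of hundreds of thousands of records, or the scientific
adequacy of any particular translation table. The merge, overlay and
matching semantics are exercised exhaustively; the reference inputs a
real run depends on remain the user's responsibility.

## Numerical and degenerate-input choices

* Overlap tolerance for the location layer: 1e-6 km² interior overlap
  (equal-area); edge/vertex contact is always legal.
* Overlay areas are compared in an equal-area projection only when the
  minimum-fraction threshold is enabled; the positive-area predicate
  itself is projection-free.
* Empty datasets are legal everywhere: validation of empty tables passes
  vacuously, summaries report counts of 0 with absent percentages.
* Ties in homonym resolution (several equally-consistent candidates)
  abstain rather than picking by key order.
* Invalid polygon geometries are repaired (`make_valid`) where possible,
  otherwise skipped and logged.
* Output files are written with a fixed column order, RFC-4180 quoting
  and `\n` line endings; reruns on identical input are byte-identical.

## Problem sizes

The shipped test suite and the acceptance script run the full pipeline on
the default fixture set (≈60 backbone names, 9 locations, 5 sources,
≈80 raw rows merging to 57 records), the merge oracle on 100 random
inputs of up to 200 records, and the overlay oracle on 20 random features
against a 0.02-degree raster — a few seconds in total on one CPU. These
sizes were chosen as the smallest that exercise every rule at least once
while keeping the ledger hand-checkable.

## Known limitations

* Vector I/O is GeoJSON (and delimited translation tables); geopackage
  and shapefile containers must be converted upstream.
* The live backbone adapter caches service responses to disk for
  reproducibility but performs no rate limiting or batch querying.
* Pathway standardization is strict table lookup; no inference from free
  text is attempted.
* The location layer is an input; the package neither downloads nor edits
  administrative boundaries.
* Fractional range-map coverage per location is not reported; a feature
  either counts for a location (positive-area overlap above the optional
  threshold) or it does not.
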