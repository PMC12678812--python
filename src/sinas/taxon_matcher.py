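"""Taxonomic name harmonization against a pluggable backbone.

Names are resolved through a cascade: exact lookup first; if the exact hit
is a synonym it is replaced by its accepted name and flagged; if several
taxa share the name (homonyms) the source's hints (author, kingdom,
taxonomic group) arbitrate; only when no exact hit exists is fuzzy
matching consulted, and only a sole candidate at the backbone's full
confidence (100) is accepted — minor spelling errors are recovered,
anything riskier is left unmatched. Unmatched names stay in the dataset
under their verbatim spelling with status MISSING.

Two backbones are provided: :class:`LocalBackbone`, a delimited-text
table used by all tests and offline runs, and
:class:`GbifServiceBackbone`, an adapter for the live GBIF species-match
service with an on-disk response cache so runs are reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from sinas._text import collapse_ws, normalize

HIGHER_RANKS = ["species", "genus", "family", "order", "class", "phylum", "kingdom"]

_INFRASPECIFIC_MARKERS = {"var.", "subsp.", "ssp.", "f.", "forma", "cv."}


class BackboneUnavailableError(RuntimeError):
    """The backbone service could not be reached; retryable, distinct from MISSING."""


@dataclass
class BackboneEntry:
    usage_key: int
    scientific_name: str
    canonical_name: str
    authorship: str
    rank: str
    status: str  # ACCEPTED | SYNONYM | DOUBTFUL
    accepted_usage_key: int
    higher: dict[str, str] = field(default_factory=dict)


@dataclass
class TaxonMatch:
    verbatim_name: str
    taxon: str
    scientific_name: str | None = None
    status: str = "MISSING"  # ACCEPTED | SYNONYM | MISSING
    status_synonym: str | None = None
    match_type: str | None = None  # EXACT | FUZZY
    rank: str | None = None
    usage_key: int | None = None
    note: str | None = None
    higher: dict[str, str] = field(default_factory=dict)
    taxa_group: str | None = None


def _match_key(name: str) -> str:
    """Matching key: hybrid markers stripped, case-folded, diacritics-free."""
    cleaned = name.replace("×", " ")
    cleaned = re.sub(r"(?<![A-Za-z])x(?=\s)", " ", cleaned)
    return normalize(cleaned)


def damerau_levenshtein(a: str, b: str, cutoff: int = 3) -> int:
    """Optimal-string-alignment Damerau–Levenshtein distance with early exit.

    Returns ``cutoff`` when the true distance is >= cutoff.
    """
    if a == b:
        return 0
    if abs(len(a) - len(b)) >= cutoff:
        return cutoff
    prev2: list[int] | None = None
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cost = 0 if ca == cb else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ca == b[j - 2] and cb == a[i - 2]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if min(cur) >= cutoff:
            return cutoff
        prev2, prev = prev, cur
    return min(prev[-1], cutoff)


class LocalBackbone:
    """Table-backed taxonomy backbone (delimited text).

    Columns: usage_key, scientific_name, canonical_name, authorship, rank,
    status, accepted_usage_key, kingdom, phylum, class, order, family,
    genus, species.

    Fuzzy confidence is deterministic: 100 iff the query has a unique
    candidate within Damerau–Levenshtein distance 1 of a canonical name
    and no other candidate within distance 2; otherwise confidence decays
    with distance and full confidence is never awarded.
    """

    def __init__(self, table: pd.DataFrame):
        self._entries: dict[int, BackboneEntry] = {}
        self._exact: dict[str, list[int]] = {}
        for _, row in table.iterrows():
            entry = BackboneEntry(
                usage_key=int(row["usage_key"]),
                scientific_name=str(row["scientific_name"]),
                canonical_name=str(row["canonical_name"]),
                authorship=str(row.get("authorship", "") or ""),
                rank=str(row["rank"]),
                status=str(row["status"]),
                accepted_usage_key=int(row["accepted_usage_key"]),
                higher={r: str(row[r]) for r in HIGHER_RANKS if str(row.get(r, "") or "").strip()},
            )
            self._entries[entry.usage_key] = entry
            for key in {_match_key(entry.canonical_name), _match_key(entry.scientific_name)}:
                self._exact.setdefault(key, []).append(entry.usage_key)

    @classmethod
    def from_file(cls, path: str | Path) -> "LocalBackbone":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def lookup_exact(self, name: str) -> list[BackboneEntry]:
        keys = self._exact.get(_match_key(name), [])
        return [self._entries[k] for k in sorted(keys)]

    def lookup_fuzzy(self, name: str) -> list[tuple[BackboneEntry, int]]:
        query = _match_key(name)
        by_dist: dict[int, list[BackboneEntry]] = {1: [], 2: []}
        seen: set[int] = set()
        for entry in self._entries.values():
            if entry.usage_key in seen:
                continue
            d = damerau_levenshtein(query, _match_key(entry.canonical_name), cutoff=3)
            if 0 < d <= 2:
                by_dist[d].append(entry)
                seen.add(entry.usage_key)
        results: list[tuple[BackboneEntry, int]] = []
        sole_close = len(by_dist[1]) == 1 and not by_dist[2]
        for d in (1, 2):
            for entry in sorted(by_dist[d], key=lambda e: e.usage_key):
                confidence = 100 if (d == 1 and sole_close) else max(0, 95 - 10 * d)
                results.append((entry, confidence))
        return results

    def resolve(self, usage_key: int) -> BackboneEntry:
        return self._entries[usage_key]


# --- taxa groups ------------------------------------------------------------

# Ordered rule table (rank, value, group); first match wins. The 20 labels
# follow common biogeographic grouping practice; several groups are
# ecological rather than monophyletic (e.g. Algae, Fishes).
DEFAULT_TAXA_GROUP_RULES: list[tuple[str, str, str]] = [
    ("class", "Aves", "Birds"),
    ("class", "Mammalia", "Mammals"),
    ("class", "Amphibia", "Amphibians"),
    ("class", "Reptilia", "Reptiles"),
    ("class", "Squamata", "Reptiles"),
    ("class", "Testudines", "Reptiles"),
    ("class", "Crocodylia", "Reptiles"),
    ("class", "Actinopterygii", "Fishes"),
    ("class", "Elasmobranchii", "Fishes"),
    ("class", "Sarcopterygii", "Fishes"),
    ("class", "Myxini", "Fishes"),
    ("class", "Petromyzonti", "Fishes"),
    ("class", "Insecta", "Insects"),
    ("class", "Arachnida", "Arachnids"),
    ("class", "Malacostraca", "Crustaceans"),
    ("class", "Branchiopoda", "Crustaceans"),
    ("class", "Hexanauplia", "Crustaceans"),
    ("class", "Maxillopoda", "Crustaceans"),
    ("class", "Ostracoda", "Crustaceans"),
    ("phylum", "Arthropoda", "Other arthropods"),
    ("phylum", "Mollusca", "Molluscs"),
    ("class", "Clitellata", "Annelids"),
    ("class", "Polychaeta", "Annelids"),
    ("phylum", "Annelida", "Annelids"),
    ("phylum", "Nematoda", "nematodes, platyhelminthes and other worms"),
    ("phylum", "Platyhelminthes", "nematodes, platyhelminthes and other worms"),
    ("phylum", "Acanthocephala", "nematodes, platyhelminthes and other worms"),
    ("phylum", "Tracheophyta", "Vascular plants"),
    ("phylum", "Bryophyta", "Bryophytes"),
    ("phylum", "Marchantiophyta", "Bryophytes"),
    ("phylum", "Anthocerotophyta", "Bryophytes"),
    ("phylum", "Chlorophyta", "Algae"),
    ("phylum", "Rhodophyta", "Algae"),
    ("phylum", "Charophyta", "Algae"),
    ("kingdom", "Fungi", "Fungi"),
    ("kingdom", "Viruses", "Viruses"),
    ("kingdom", "Bacteria", "Bacteria and protozoans"),
    ("kingdom", "Protozoa", "Bacteria and protozoans"),
    ("kingdom", "Chromista", "SAR"),
    ("kingdom", "Animalia", "Other aquatic animals"),
]

VALID_RULE_RANKS = set(HIGHER_RANKS)


def assign_taxa_group(
    higher: dict[str, str],
    rule_table: list[tuple[str, str, str]] | None = None,
) -> str | None:
    """First rule whose (rank, value) matches the higher taxonomy wins."""
    if not higher:
        return None
    rules = DEFAULT_TAXA_GROUP_RULES if rule_table is None else rule_table
    for rank, value, group in rules:
        if rank not in VALID_RULE_RANKS:
            raise ValueError(f"taxa-group rule references unknown rank '{rank}'")
        if normalize(higher.get(rank, "")) == normalize(value):
            return group
    return None


def strip_authority(scientific_name: str) -> str:
    """Remove authority and date tokens, keeping infraspecific markers.

    'Lonchura malacca (Linnaeus, 1766)' -> 'Lonchura malacca';
    'Abies alba Mill.' -> 'Abies alba';
    'Poa annua var. annua L.' -> 'Poa annua var. annua'.
    """
    tokens = collapse_ws(scientific_name).split(" ")
    if not tokens or not tokens[0]:
        return ""
    kept = [tokens[0]]
    expect_epithet = False
    for tok in tokens[1:]:
        low = tok.lower()
        if low in _INFRASPECIFIC_MARKERS or tok == "×" or low == "x":
            kept.append(tok)
            expect_epithet = True
        elif tok[:1].isalpha() and tok[:1].islower() and re.fullmatch(r"[a-z\-]+", low):
            kept.append(tok)
            expect_epithet = False
        else:
            if expect_epithet:
                kept.pop()  # dangling marker with no epithet
            break
    return " ".join(kept)


def resolve_homonym(
    candidates: list[BackboneEntry],
    hints: dict[str, str] | None,
) -> BackboneEntry | None:
    """Arbitrate between same-named backbone entries using source hints.

    Hints apply in order author -> kingdom -> group; each provided hint
    discards non-conforming candidates. A unique survivor is returned;
    zero or several survivors mean the homonym stays unresolved (None).
    """
    hints = hints or {}
    survivors = list(candidates)

    def _filter(pred) -> None:
        nonlocal survivors
        if len(survivors) <= 1:
            return
        narrowed = [c for c in survivors if pred(c)]
        if narrowed:
            survivors = narrowed

    if hints.get("author"):
        _filter(lambda c: normalize(c.authorship) == normalize(hints["author"]))
    if hints.get("kingdom"):
        _filter(lambda c: normalize(c.higher.get("kingdom", "")) == normalize(hints["kingdom"]))
    if hints.get("group"):
        _filter(lambda c: normalize(assign_taxa_group(c.higher) or "") == normalize(hints["group"]))
    return survivors[0] if len(survivors) == 1 else None


def _accepted_match(
    verbatim: str,
    entry: BackboneEntry,
    backbone,
    match_type: str,
    note: str | None = None,
) -> TaxonMatch:
    """Build the TaxonMatch for an entry, resolving synonyms to accepted names."""
    if entry.status == "SYNONYM":
        accepted = backbone.resolve(entry.accepted_usage_key)
        return TaxonMatch(
            verbatim_name=verbatim,
            taxon=accepted.canonical_name,
            scientific_name=accepted.scientific_name,
            status="SYNONYM",
            status_synonym=accepted.status,
            match_type=match_type,
            rank=accepted.rank,
            usage_key=accepted.usage_key,
            note=note or "Accepted name found on GBIF",
            higher=dict(accepted.higher),
            taxa_group=assign_taxa_group(accepted.higher),
        )
    return TaxonMatch(
        verbatim_name=verbatim,
        taxon=entry.canonical_name,
        scientific_name=entry.scientific_name,
        status="ACCEPTED",
        match_type=match_type,
        rank=entry.rank,
        usage_key=entry.usage_key,
        note=note,
        higher=dict(entry.higher),
        taxa_group=assign_taxa_group(entry.higher),
    )


def _missing(verbatim: str, note: str | None = None) -> TaxonMatch:
    return TaxonMatch(verbatim_name=verbatim, taxon=verbatim, status="MISSING", note=note)


def match_taxon(
    verbatim: str,
    backbone,
    hints: dict[str, str] | None = None,
) -> TaxonMatch:
    """Resolve one verbatim name through the exact -> synonym -> fuzzy cascade.

    Whenever an exact match exists no fuzzy result is consulted. Fuzzy
    results are used only when a single candidate reaches confidence 100.
    Unresolved homonyms abstain: the match is MISSING-like with note
    "Homonym in GBIF" — picking a wrong taxon is worse than none.
    """
    if not verbatim.strip():
        raise ValueError("verbatim taxon name must be non-empty")
    hints = hints or {}

    exact = backbone.lookup_exact(verbatim)
    if exact:
        return _resolve_hits(verbatim, exact, backbone, hints, "EXACT")

    fuzzy = backbone.lookup_fuzzy(verbatim)
    full = [entry for entry, conf in fuzzy if conf == 100]
    if len(full) == 1:
        return _resolve_hits(verbatim, full, backbone, hints, "FUZZY")
    return _missing(verbatim)


def _resolve_hits(
    verbatim: str,
    hits: list[BackboneEntry],
    backbone,
    hints: dict[str, str],
    match_type: str,
) -> TaxonMatch:
    accepted_like = [e for e in hits if e.status in ("ACCEPTED", "DOUBTFUL")]
    synonyms = [e for e in hits if e.status == "SYNONYM"]

    if len(accepted_like) == 1:
        return _accepted_match(verbatim, accepted_like[0], backbone, match_type)
    if len(accepted_like) > 1:
        chosen = resolve_homonym(accepted_like, hints)
        if chosen is None:
            return _missing(verbatim, note="Homonym in GBIF")
        match = _accepted_match(verbatim, chosen, backbone, match_type, note="Homonym in GBIF")
        return match

    # synonym-only hits
    accepted_keys = sorted({e.accepted_usage_key for e in synonyms})
    if len(accepted_keys) == 1:
        note = "Multiple synonyms in GBIF" if len(synonyms) > 1 else None
        return _accepted_match(verbatim, synonyms[0], backbone, match_type, note=note)
    chosen = resolve_homonym(synonyms, hints)
    if chosen is not None:
        return _accepted_match(verbatim, chosen, backbone, match_type)
    return _missing(verbatim, note="Multiple accepted names for synonym in GBIF")


def build_taxa_list(matches: list[TaxonMatch]) -> pd.DataFrame:
    """One taxa-table row per distinct verbatim name (first match wins).

    The original name is preserved under the published header
    ``verbatimTaxonRank`` (which, despite its name, holds the original
    taxon name as supplied by the source). taxonIDs are assigned later by
    the integrator.
    """
    rows: list[dict] = []
    seen: set[str] = set()
    for m in matches:
        if m.verbatim_name in seen:
            continue
        seen.add(m.verbatim_name)
        row = {
            "scientificName": m.scientific_name or "",
            "verbatimTaxonRank": m.verbatim_name,
            "taxon": m.taxon,
            "GBIFstatus": m.status,
            "GBIFstatus_Synonym": m.status_synonym or "",
            "GBIFmatchtype": m.match_type or "",
            "GBIFtaxonRank": m.rank or "",
            "GBIFusageKey": "" if m.usage_key is None else str(m.usage_key),
            "GBIFnote": m.note or "",
            "taxaGroup": m.taxa_group or "",
        }
        for rank in HIGHER_RANKS:
            row[rank] = m.higher.get(rank, "")
        rows.append(row)
    columns = [
        "scientificName", "verbatimTaxonRank", "taxon", "GBIFstatus", "GBIFstatus_Synonym",
        "GBIFmatchtype", "GBIFtaxonRank", "GBIFusageKey", "GBIFnote",
        *HIGHER_RANKS, "taxaGroup",
    ]
    return pd.DataFrame(rows, columns=columns)


class GbifServiceBackbone:
    """Adapter for the GBIF species-match web service with a disk cache.

    Responses are cached in an append-only JSON file keyed by
    (query name, kingdom hint) so a completed run is reproducible offline.
    With ``offline=True`` a cache miss raises
    :class:`BackboneUnavailableError` instead of touching the network.
    """

    API_URL = "https://api.gbif.org/v1/species/match"

    def __init__(self, cache_path: str | Path, offline: bool = False):
        self.cache_path = Path(cache_path)
        self.offline = offline
        self._cache: dict[str, dict] = {}
        if self.cache_path.exists():
            self._cache = json.loads(self.cache_path.read_text(encoding="utf-8"))

    @staticmethod
    def _key(name: str, kingdom: str | None) -> str:
        return f"{normalize(name)}|kingdom={normalize(kingdom or '')}"

    def _fetch(self, name: str, kingdom: str | None) -> dict:
        import urllib.parse
        import urllib.request

        params = {"name": name}
        if kingdom:
            params["kingdom"] = kingdom
        url = f"{self.API_URL}?{urllib.parse.urlencode(params)}"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except Exception as exc:  # noqa: BLE001 — any transport failure is retryable
            raise BackboneUnavailableError(str(exc)) from exc

    def match_name(self, name: str, kingdom: str | None = None) -> TaxonMatch:
        key = self._key(name, kingdom)
        if key not in self._cache:
            if self.offline:
                raise BackboneUnavailableError(f"no cached response for {key!r}")
            self._cache[key] = self._fetch(name, kingdom)
            self.cache_path.write_text(
                json.dumps(self._cache, indent=1, sort_keys=True), encoding="utf-8"
            )
        return self._parse(name, self._cache[key])

    @staticmethod
    def _parse(verbatim: str, resp: dict) -> TaxonMatch:
        match_type = resp.get("matchType", "NONE")
        confidence = int(resp.get("confidence", 0))
        if match_type not in ("EXACT", "FUZZY") or (match_type == "FUZZY" and confidence < 100):
            return _missing(verbatim)
        higher = {r: resp[r] for r in HIGHER_RANKS if resp.get(r)}
        is_synonym = bool(resp.get("synonym", False))
        usage_key = resp.get("acceptedUsageKey", resp.get("usageKey"))
        canonical = resp.get("canonicalName", "")
        accepted_name = resp.get("accepted", resp.get("scientificName", ""))
        return TaxonMatch(
            verbatim_name=verbatim,
            taxon=strip_authority(accepted_name) if is_synonym else canonical,
            scientific_name=accepted_name,
            status="SYNONYM" if is_synonym else "ACCEPTED",
            status_synonym=resp.get("status") if is_synonym else None,
            match_type=match_type,
            rank=resp.get("rank"),
            usage_key=None if usage_key is None else int(usage_key),
            note="Accepted name found on GBIF" if is_synonym else None,
            higher=higher,
            taxa_group=assign_taxa_group(higher),
        )
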