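"""Synthetic fixture generation with a ground-truth ledger.

The generator fabricates everything a full run consumes — a taxonomy
backbone, a location layer with translation table, and several source
datasets in deliberately different dialects — together with a ledger of
the exact output the pipeline must produce. Fixtures exercise code paths,
not ecology: taxon names are pronounceable synthetic binomials (never
real names), locations are unit grid squares, and every structural
anomaly the workflow must survive is planted on purpose:

* synonym, homonym and misspelled taxon names (with a manifest of the
  intended targets);
* binary-coded establishment flags with an unknown code;
* locations scattered across several columns, subdivision-level records,
  alternative spellings and one unmatched location;
* a polygon range-map source with origin codes, including a feature that
  only touches a location's boundary;
* duplicate records, conflicting first-record years, an
  introduced+uncertain pair, a native+introduced pair, and unmatched
  status/pathway/date terms.

Everything derives from a single seed: the same seed yields byte-identical
files and ledger.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import pandas as pd
import yaml

from sinas.data_model import RECORD_COLUMNS, SEP, TAXA_COLUMNS
from sinas.taxon_matcher import HIGHER_RANKS, damerau_levenshtein

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

_LINEAGES = [
    {"kingdom": "Animalia", "phylum": "Chordata", "class": "Aves", "order": "Passeriformes", "group": "Birds"},
    {"kingdom": "Animalia", "phylum": "Chordata", "class": "Mammalia", "order": "Rodentia", "group": "Mammals"},
    {"kingdom": "Plantae", "phylum": "Tracheophyta", "class": "Magnoliopsida", "order": "Asterales", "group": "Vascular plants"},
    {"kingdom": "Animalia", "phylum": "Arthropoda", "class": "Insecta", "order": "Coleoptera", "group": "Insects"},
    {"kingdom": "Fungi", "phylum": "Ascomycota", "class": "Sordariomycetes", "order": "Hypocreales", "group": "Fungi"},
    {"kingdom": "Animalia", "phylum": "Chordata", "class": "Actinopterygii", "order": "Perciformes", "group": "Fishes"},
    {"kingdom": "Animalia", "phylum": "Mollusca", "class": "Gastropoda", "order": "Stylommatophora", "group": "Molluscs"},
]

_AUTHORS = ["Brel", "Corvan", "Dastel", "Fenor", "Galdin", "Harst", "Lomer", "Norvell"]


@dataclass
class FixtureSpec:
    seed: int = 42
    n_true_taxa: int = 60
    synonym_fraction: float = 0.15
    homonym_fraction: float = 0.05
    misspelling_fraction: float = 0.10
    n_locations: int = 9  # perfect square (unit grid)
    n_sources: int = 5

    def __post_init__(self) -> None:
        if self.synonym_fraction + self.homonym_fraction + self.misspelling_fraction > 1:
            raise ValueError("synonym + homonym + misspelling fractions must be <= 1")
        if int(math.isqrt(self.n_locations)) ** 2 != self.n_locations:
            raise ValueError("n_locations must be a perfect square")


@dataclass
class GroundTruthLedger:
    """Exact expected pipeline output for one fixture set (all-string frames,
    matching the serialized form of the output tables)."""

    records: pd.DataFrame
    taxa: pd.DataFrame
    unmatched_terms: pd.DataFrame
    unmatched_locations: pd.DataFrame
    exclusions: pd.DataFrame
    summary_counts: dict
    ingest_drops: dict = dataclass_field(default_factory=dict)


def _syllables(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))


def _binomial(rng: random.Random) -> str:
    return _syllables(rng, 3).capitalize() + " " + _syllables(rng, 3)


# --- backbone ---------------------------------------------------------------


def generate_backbone(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict]:
    """Write the fixture backbone table and return (path, name manifest).

    The manifest records every accepted name with its lineage, the
    synonym -> accepted mapping, the homonym pairs (with both kingdoms),
    and the planted misspellings with their intended targets — each
    misspelling is guaranteed to sit at edit distance 1 from its target
    and at distance >= 3 from every other backbone name, so the fixture
    backbone's confidence rule awards it exactly 100.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    names: set[str] = set()
    accepted: list[dict] = []
    while len(accepted) < spec.n_true_taxa:
        name = _binomial(rng)
        if name in names:
            continue
        names.add(name)
        lineage = _LINEAGES[len(accepted) % len(_LINEAGES)]
        author = f"({rng.choice(_AUTHORS)}, {rng.randint(1758, 1950)})"
        accepted.append({"canonical": name, "authorship": author, "lineage": lineage})

    n_syn = round(spec.synonym_fraction * spec.n_true_taxa)
    n_hom = round(spec.homonym_fraction * spec.n_true_taxa)
    n_mis = round(spec.misspelling_fraction * spec.n_true_taxa)

    synonyms: list[dict] = []
    while len(synonyms) < n_syn:
        name = _binomial(rng)
        if name in names:
            continue
        names.add(name)
        target = accepted[len(synonyms) % spec.n_true_taxa]
        synonyms.append({"canonical": name, "accepted_canonical": target["canonical"]})

    # homonym pairs: duplicate the canonical under a different kingdom
    homonyms: list[dict] = []
    for i in range(n_hom):
        target = accepted[(i * 7 + 3) % spec.n_true_taxa]
        alt_lineage = next(
            lin for lin in _LINEAGES if lin["kingdom"] != target["lineage"]["kingdom"]
        )
        homonyms.append(
            {
                "canonical": target["canonical"],
                "kingdoms": [target["lineage"]["kingdom"], alt_lineage["kingdom"]],
                "alt_lineage": alt_lineage,
                "alt_authorship": f"({rng.choice(_AUTHORS)}, {rng.randint(1758, 1950)})",
            }
        )
    homonym_names = {h["canonical"] for h in homonyms}
    synonym_names = {s["canonical"] for s in synonyms}

    def _unique_at_distance(candidate: str, target: str) -> bool:
        if candidate in names:
            return False
        for other in names:
            if other == target:
                continue
            if damerau_levenshtein(candidate.lower(), other.lower(), cutoff=3) < 3:
                return False
        return damerau_levenshtein(candidate.lower(), target.lower(), cutoff=3) == 1

    misspellings: list[dict] = []
    pool = [a["canonical"] for a in accepted if a["canonical"] not in homonym_names]
    idx = 0
    while len(misspellings) < n_mis and idx < len(pool):
        target = pool[idx]
        idx += 1
        genus, epithet = target.split(" ", 1)
        wrong = None
        for pos in range(1, len(epithet)):
            for letter in _CONSONANTS + _VOWELS:
                cand = genus + " " + epithet[:pos] + letter + epithet[pos + 1 :]
                if cand != target and _unique_at_distance(cand, target):
                    wrong = cand
                    break
            if wrong:
                break
        if wrong:
            misspellings.append({"wrong": wrong, "target": target})

    # unmatched names: far (distance >= 3) from everything in the backbone
    unmatched: list[str] = []
    while len(unmatched) < 2:
        name = "Zyx" + _syllables(rng, 2) + "qu " + "zq" + _syllables(rng, 3)
        if all(
            damerau_levenshtein(name.lower(), other.lower(), cutoff=3) >= 3 for other in names
        ) and name not in unmatched:
            unmatched.append(name)

    rows: list[dict] = []
    key = 1000

    def _row(canonical: str, authorship: str, lineage: dict, status: str, accepted_key: int | None):
        nonlocal key
        key += 1
        genus = canonical.split(" ")[0]
        row = {
            "usage_key": key,
            "scientific_name": f"{canonical} {authorship}",
            "canonical_name": canonical,
            "authorship": authorship,
            "rank": "SPECIES",
            "status": status,
            "accepted_usage_key": accepted_key if accepted_key is not None else key,
            "kingdom": lineage["kingdom"],
            "phylum": lineage["phylum"],
            "class": lineage["class"],
            "order": lineage["order"],
            "family": genus + "idae",
            "genus": genus,
            "species": canonical,
        }
        rows.append(row)
        return key

    accepted_key_by_name: dict[str, int] = {}
    for entry in accepted:
        k = _row(entry["canonical"], entry["authorship"], entry["lineage"], "ACCEPTED", None)
        entry["usage_key"] = k
        accepted_key_by_name[entry["canonical"]] = k
    for syn in synonyms:
        target_key = accepted_key_by_name[syn["accepted_canonical"]]
        syn["usage_key"] = _row(
            syn["canonical"], "(Synon., 1900)", {"kingdom": "", "phylum": "", "class": "", "order": ""}
            | next(e["lineage"] for e in accepted if e["canonical"] == syn["accepted_canonical"]),
            "SYNONYM",
            target_key,
        )
    for hom in homonyms:
        hom["alt_usage_key"] = _row(
            hom["canonical"], hom["alt_authorship"], hom["alt_lineage"], "ACCEPTED", None
        )

    frame = pd.DataFrame(rows)
    path = out_dir / "backbone.csv"
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    manifest = {
        "accepted": accepted,
        "synonyms": synonyms,
        "homonyms": homonyms,
        "misspellings": misspellings,
        "unmatched": unmatched,
    }
    return path, manifest


# --- locations --------------------------------------------------------------


def generate_locations(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path, list[dict]]:
    """Write the grid location layer (GeoJSON) and the translation table.

    Locations are disjoint unit squares. Some get an alternative spelling
    and some a pair of subdivision names; two aggregation schemes are
    included ('custom' by column band, 'latband' by row band).
    """
    rng = random.Random(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = math.isqrt(spec.n_locations)

    infos: list[dict] = []
    used: set[str] = set()
    for i in range(spec.n_locations):
        while True:
            name = _syllables(rng, 3).capitalize() + "land"
            if name not in used:
                used.add(name)
                break
        col, row = i % g, i // g
        info = {
            "name": name,
            "location_id": 10 + i,
            "cell": (col, row),
            "alternatives": [],
            "subdivisions": [],
            "custom": f"Band-{chr(ord('A') + col)}",
            "latband": f"Lat-{row}",
        }
        if i % 3 == 0:
            info["alternatives"].append(name + " Republic")
        if i % 4 == 1:
            info["subdivisions"] = [name + " North", name + " South"]
        infos.append(info)

    features = []
    for info in infos:
        c, r = info["cell"]
        ring = [[c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]]
        features.append(
            {
                "type": "Feature",
                "properties": {"location": info["name"]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    geojson_path = out_dir / "locations.geojson"
    geojson_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
        encoding="utf-8",
    )

    table = pd.DataFrame(
        [
            {
                "location": info["name"],
                "locationID": info["location_id"],
                "alternatives": "|".join(info["alternatives"]),
                "subdivisions": "|".join(info["subdivisions"]),
                "custom": info["custom"],
                "latband": info["latband"],
            }
            for info in infos
        ]
    )
    table_path = out_dir / "locations.csv"
    table.to_csv(table_path, index=False, lineterminator="\n", encoding="utf-8")
    return geojson_path, table_path, infos


# --- sources + ledger -------------------------------------------------------


@dataclass
class _Intent:
    """One planted occurrence with its fully resolved expectation."""

    source: str
    verbatim_taxon: str
    taxon: str  # expected accepted (or verbatim) name
    location_id: int | None
    location_name: str | None
    establishment: str | None
    occurrence: str | None = None
    degree: str | None = None
    pathway: str | None = None
    habitat: tuple[str, ...] = ()
    year: int | None = None


def _expected_taxa_row(kind: str, verbatim: str, info: dict) -> dict:
    """Build one expected taxa-table row (string form, no taxonID yet)."""
    row = {c: "" for c in TAXA_COLUMNS if c != "taxonID"}
    row["verbatimTaxonRank"] = verbatim
    if kind == "missing":
        row["taxon"] = verbatim
        row["GBIFstatus"] = "MISSING"
        row["GBIFnote"] = info.get("note", "")
        return row
    lineage = info["lineage"]
    canonical = info["canonical"]
    genus = canonical.split(" ")[0]
    row.update(
        {
            "scientificName": f"{canonical} {info['authorship']}",
            "taxon": canonical,
            "GBIFstatus": info["status"],
            "GBIFstatus_Synonym": info.get("status_synonym", ""),
            "GBIFmatchtype": info["match_type"],
            "GBIFtaxonRank": "SPECIES",
            "GBIFusageKey": str(info["usage_key"]),
            "GBIFnote": info.get("note", ""),
            "species": canonical,
            "genus": genus,
            "family": genus + "idae",
            "order": lineage["order"],
            "class": lineage["class"],
            "phylum": lineage["phylum"],
            "kingdom": lineage["kingdom"],
            "taxaGroup": lineage["group"],
        }
    )
    return row


def generate_sources(
    spec: FixtureSpec,
    manifest: dict,
    location_infos: list[dict],
    out_dir: str | Path,
) -> tuple[list[dict], GroundTruthLedger]:
    """Write the source files + configs and compute the ground-truth ledger.

    The ledger is computed from the planting plan itself with plain
    dictionary arithmetic — it never calls the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accepted = manifest["accepted"]
    by_name = {a["canonical"]: a for a in accepted}
    homonym_names = {h["canonical"] for h in manifest["homonyms"]}
    plain = [a for a in accepted if a["canonical"] not in homonym_names]
    synonyms = manifest["synonyms"]
    misspellings = manifest["misspellings"]
    homonyms = manifest["homonyms"]
    unmatched_names = manifest["unmatched"]
    locs = location_infos
    loc_by_name = {i["name"]: i for i in locs}

    intents: list[_Intent] = []
    taxa_expect: dict[str, dict] = {}  # verbatim -> expected taxa row
    unmatched_terms: dict[tuple[str, str, str], int] = {}
    unmatched_locations: dict[tuple[str, str], int] = {}
    exclusions: dict[tuple[str, str, str, str], int] = {}
    ingest_drops: dict[tuple[str, str], int] = {}

    def miss(field: str, source: str, verbatim: str) -> None:
        unmatched_terms[(field, source, verbatim)] = (
            unmatched_terms.get((field, source, verbatim), 0) + 1
        )

    def expect_plain(entry: dict, verbatim: str | None = None, match_type: str = "EXACT", note: str = "") -> str:
        v = verbatim or entry["canonical"]
        taxa_expect.setdefault(
            v,
            _expected_taxa_row(
                "match",
                v,
                {
                    "canonical": entry["canonical"],
                    "authorship": entry["authorship"],
                    "lineage": entry["lineage"],
                    "status": "ACCEPTED",
                    "match_type": match_type,
                    "usage_key": entry["usage_key"],
                    "note": note,
                },
            ),
        )
        return entry["canonical"]

    def expect_synonym(syn: dict) -> str:
        target = by_name[syn["accepted_canonical"]]
        taxa_expect.setdefault(
            syn["canonical"],
            _expected_taxa_row(
                "match",
                syn["canonical"],
                {
                    "canonical": target["canonical"],
                    "authorship": target["authorship"],
                    "lineage": target["lineage"],
                    "status": "SYNONYM",
                    "status_synonym": "ACCEPTED",
                    "match_type": "EXACT",
                    "usage_key": target["usage_key"],
                    "note": "Accepted name found on GBIF",
                },
            ),
        )
        return target["canonical"]

    def expect_missing(verbatim: str, note: str = "") -> str:
        taxa_expect.setdefault(verbatim, _expected_taxa_row("missing", verbatim, {"note": note}))
        return verbatim

    citations = {
        "ALIEN-CHK": "Fixture Consortium. Alien checklist fixture. SynthData Repository (2026).",
        "NATBIN": "Fixture Consortium. Binary-coded distribution fixture. SynthData Repository (2026).",
        "MULTI": "Fixture Consortium. Multi-column checklist fixture. SynthData Repository (2026).",
        "RANGES": "Fixture Consortium. Range-map fixture. SynthData Repository (2026).",
        "MIXED": "Fixture Consortium. Mixed-scope checklist fixture. SynthData Repository (2026).",
    }

    # ---- source 1: ALIEN-CHK (alien scope, plain checklist) ----------------
    date_cycle = [
        ("1950", 1950),
        ("1900-1910", 1905),
        ("1987-06-01", 1987),
        ("c. 1850", 1850),
        ("1920s", 1920),
        ("", None),
        ("unknown date", None),
    ]
    presence_cycle = [("extant", "present"), ("", None), ("eradicated", "absent")]
    degree_cycle = [
        ("established outdoors", "established"),
        ("", None),
        ("naturalized", "established"),
        ("invasive (high impact)", "invasive"),
    ]
    chk_rows: list[dict] = []
    chk_taxa = plain[:25]
    for i, entry in enumerate(chk_taxa):
        taxon = expect_plain(entry)
        loc = locs[i % len(locs)]
        date_v, date_e = date_cycle[i % len(date_cycle)]
        pres_v, pres_e = presence_cycle[i % len(presence_cycle)]
        deg_v, deg_e = degree_cycle[i % len(degree_cycle)]
        if date_v == "unknown date":
            miss("eventDate", "ALIEN-CHK", date_v)
        chk_rows.append(
            {
                "species": entry["canonical"],
                "area": loc["name"],
                "first_record": date_v,
                "presence": pres_v,
                "invasion_degree": deg_v,
                "introduction_pathway": "",
            }
        )
        intents.append(
            _Intent(
                "ALIEN-CHK", entry["canonical"], taxon, loc["location_id"], loc["name"],
                "introduced", pres_e, deg_e, None, (), date_e,
            )
        )
    # duplicates with conflicting years and occurrence conflict
    dup = chk_taxa[0]
    dup_loc = locs[0]
    for date_v, date_e, pres_v, pres_e in [
        ("1903", 1903, "eradicated", "absent"),
        ("1950", 1950, "extant", "present"),
    ]:
        chk_rows.append(
            {
                "species": dup["canonical"],
                "area": dup_loc["name"],
                "first_record": date_v,
                "presence": pres_v,
                "invasion_degree": "",
                "introduction_pathway": "",
            }
        )
        intents.append(
            _Intent(
                "ALIEN-CHK", dup["canonical"], dup["canonical"], dup_loc["location_id"],
                dup_loc["name"], "introduced", pres_e, None, None, (), date_e,
            )
        )
    # empty-taxon row: dropped at ingest
    chk_rows.append(
        {"species": "", "area": locs[1]["name"], "first_record": "", "presence": "",
         "invasion_degree": "", "introduction_pathway": ""}
    )
    ingest_drops[("ALIEN-CHK", "empty_taxon")] = 1
    # introduced half of the introduced+uncertain pair
    pair_iu = plain[25]
    loc_iu = locs[3]
    chk_rows.append(
        {"species": pair_iu["canonical"], "area": loc_iu["name"], "first_record": "1961",
         "presence": "extant", "invasion_degree": "established outdoors", "introduction_pathway": ""}
    )
    intents.append(
        _Intent("ALIEN-CHK", pair_iu["canonical"], expect_plain(pair_iu), loc_iu["location_id"],
                loc_iu["name"], "introduced", "present", "established", None, (), 1961)
    )
    # introduced half of the native+introduced pair
    pair_ni = plain[26]
    loc_ni = locs[2]
    chk_rows.append(
        {"species": pair_ni["canonical"], "area": loc_ni["name"], "first_record": "",
         "presence": "", "invasion_degree": "", "introduction_pathway": ""}
    )
    intents.append(
        _Intent("ALIEN-CHK", pair_ni["canonical"], expect_plain(pair_ni), loc_ni["location_id"],
                loc_ni["name"], "introduced", None, None, None, (), None)
    )
    pd.DataFrame(chk_rows).to_csv(
        out_dir / "alien_chk.csv", index=False, lineterminator="\n", encoding="utf-8"
    )

    # ---- source 2: NATBIN (binary establishment coding) --------------------
    nat_rows: list[dict] = []
    nat_taxa = plain[20:33]
    for i, entry in enumerate(nat_taxa):
        taxon = expect_plain(entry)
        loc = locs[(i * 2) % len(locs)]
        flag = "0" if i % 3 != 2 else "1"  # 0 -> native, 1 -> introduced
        nat_rows.append(
            {"name": entry["canonical"], "region": loc["name"], "introduced": flag,
             "location_doubtful": ""}
        )
        intents.append(
            _Intent("NATBIN", entry["canonical"], taxon, loc["location_id"], loc["name"],
                    "native" if flag == "0" else "introduced")
        )
    # native half of the native+introduced pair
    nat_rows.append(
        {"name": pair_ni["canonical"], "region": loc_ni["name"], "introduced": "0",
         "location_doubtful": ""}
    )
    intents.append(
        _Intent("NATBIN", pair_ni["canonical"], pair_ni["canonical"], loc_ni["location_id"],
                loc_ni["name"], "native")
    )
    # doubtful rows: dropped by the drop_rule
    for entry in plain[33:35]:
        nat_rows.append(
            {"name": entry["canonical"], "region": locs[0]["name"], "introduced": "0",
             "location_doubtful": "1"}
        )
    ingest_drops[("NATBIN", "drop_rule")] = 2
    # unknown binary code: stays verbatim, fails standardization, excluded
    bad_code = plain[35]
    nat_rows.append(
        {"name": bad_code["canonical"], "region": locs[4]["name"], "introduced": "2",
         "location_doubtful": ""}
    )
    expect_plain(bad_code)
    miss("establishmentMeans", "NATBIN", "2")
    exclusions[("NATBIN", "establishmentMeans", bad_code["canonical"],
                "missing establishment after scope inheritance")] = 1
    intents.append(
        _Intent("NATBIN", bad_code["canonical"], bad_code["canonical"], locs[4]["location_id"],
                locs[4]["name"], None)
    )
    pd.DataFrame(nat_rows).to_csv(
        out_dir / "natbin.csv", index=False, lineterminator="\n", encoding="utf-8"
    )

    # ---- source 3: MULTI (multi-column locations, habitat, pathway) --------
    multi_rows: list[dict] = []
    sub_loc = next(i for i in locs if i["subdivisions"])
    alt_loc = next(i for i in locs if i["alternatives"])
    multi_specs = [
        # (taxon verbatim, resolved, island, country, pathway, habitat)
        (misspellings[0]["wrong"],
         expect_plain(by_name[misspellings[0]["target"]], verbatim=misspellings[0]["wrong"],
                      match_type="FUZZY"),
         "", locs[5]["name"], "escaped", "sea;land"),
        (synonyms[0]["canonical"], expect_synonym(synonyms[0]),
         "", locs[6]["name"], "", "fresh water"),
        (plain[36]["canonical"], expect_plain(plain[36]),
         sub_loc["subdivisions"][0], "ignored-when-island-set", "", ""),
        (plain[37]["canonical"], expect_plain(plain[37]),
         "", alt_loc["alternatives"][0], "strange pathway", "sea"),
        (plain[38]["canonical"], expect_plain(plain[38]),
         "", "Atlantis", "", ""),
        (unmatched_names[0], expect_missing(unmatched_names[0]),
         "", locs[7]["name"], "", "outer space"),
    ]
    for verbatim, resolved, island, country, pathway_v, habitat_v in multi_specs:
        multi_rows.append(
            {"taxon": verbatim, "island": island, "country": country,
             "pathway": pathway_v, "habitat": habitat_v}
        )
        if island:
            loc_id, loc_name = sub_loc["location_id"], sub_loc["name"]
        elif country == "Atlantis":
            loc_id, loc_name = None, None
            unmatched_locations[("MULTI", "Atlantis")] = 1
            exclusions[("MULTI", "location", "Atlantis", "unmatched location")] = 1
        elif country in loc_by_name:
            loc_id, loc_name = loc_by_name[country]["location_id"], country
        else:  # alternative spelling
            parent = next(i for i in locs if country in i["alternatives"])
            loc_id, loc_name = parent["location_id"], parent["name"]
        pathway_e = None
        if pathway_v == "escaped":
            pathway_e = "escape from confinement"
        elif pathway_v:
            miss("pathway", "MULTI", pathway_v)
        habitat_e: tuple[str, ...] = ()
        if habitat_v:
            mapping = {"sea": "marine", "land": "terrestrial", "fresh water": "freshwater"}
            hits = []
            for tok in habitat_v.split(";"):
                tok = tok.strip()
                if tok in mapping:
                    hits.append(mapping[tok])
                elif tok:
                    miss("habitat", "MULTI", tok)
            habitat_e = tuple(sorted(set(hits)))
        intents.append(
            _Intent("MULTI", verbatim, resolved, loc_id, loc_name, "introduced",
                    None, None, pathway_e, habitat_e, None)
        )
    # all-empty location row: dropped and counted
    multi_rows.append({"taxon": plain[39]["canonical"], "island": "", "country": "",
                       "pathway": "", "habitat": ""})
    ingest_drops[("MULTI", "empty_location")] = 1
    pd.DataFrame(multi_rows).to_csv(
        out_dir / "multi.csv", index=False, lineterminator="\n", encoding="utf-8"
    )

    # ---- source 4: RANGES (polygon range maps) -----------------------------
    def cell_rect(col: int, row: int, pad: float) -> list[list[float]]:
        return [[col + pad, row + pad], [col + 1 - pad, row + pad],
                [col + 1 - pad, row + 1 - pad], [col + pad, row + 1 - pad],
                [col + pad, row + pad]]

    g = math.isqrt(spec.n_locations)
    by_cell = {i["cell"]: i for i in locs}
    r_taxa = [plain[40], plain[41], plain[42], plain[43], plain[44]]
    features = [
        # strictly inside cell (0,0) -> one location
        {"taxon": r_taxa[0]["canonical"], "origin": "native",
         "ring": cell_rect(0, 0, 0.2), "cells": [(0, 0)]},
        # spans cells (0,0) and (1,0) -> two locations
        {"taxon": r_taxa[1]["canonical"], "origin": "native",
         "ring": [[0.3, 0.3], [1.7, 0.3], [1.7, 0.7], [0.3, 0.7], [0.3, 0.3]],
         "cells": [(0, 0), (1, 0)]},
        # reintroduced -> standardizes to native
        {"taxon": r_taxa[2]["canonical"], "origin": "reintroduced",
         "ring": cell_rect(1 % g, 1 % g, 0.25), "cells": [(1 % g, 1 % g)]},
        # vagrant origin: discarded by the origin filter
        {"taxon": r_taxa[3]["canonical"], "origin": "vagrant",
         "ring": cell_rect(0, 0, 0.3), "cells": []},
        # touches the boundary of cell (0,1) only: no record there
        {"taxon": r_taxa[4]["canonical"], "origin": "native",
         "ring": [[0.2, 0.5], [0.8, 0.5], [0.8, 1.0], [0.2, 1.0], [0.2, 0.5]],
         "cells": [(0, 0)]},
    ]
    geo_features = [
        {"type": "Feature",
         "properties": {"taxon": f["taxon"], "origin": f["origin"]},
         "geometry": {"type": "Polygon", "coordinates": [f["ring"]]}}
        for f in features
    ]
    (out_dir / "ranges.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": geo_features}, indent=1),
        encoding="utf-8",
    )
    for f in features:
        if not f["cells"]:
            continue
        entry = by_name[f["taxon"]]
        expect_plain(entry)
        for cell in f["cells"]:
            loc = by_cell[cell]
            intents.append(
                _Intent("RANGES", f["taxon"], f["taxon"], loc["location_id"], loc["name"],
                        "native")
            )

    # ---- source 5: MIXED (text establishment variants, homonyms) -----------
    mixed_rows: list[dict] = []

    def mixed_row(verbatim, resolved, loc, status_v, status_e, author="", kingdom="", year_v="",
                  year_e=None):
        mixed_rows.append(
            {"sciname": verbatim, "author": author, "kingdom": kingdom, "loc": loc["name"],
             "status": status_v, "year_introduced": year_v}
        )
        intents.append(
            _Intent("MIXED", verbatim, resolved, loc["location_id"], loc["name"], status_e,
                    None, None, None, (), year_e)
        )

    # uncertain half of the introduced+uncertain pair (merges with ALIEN-CHK)
    mixed_row(pair_iu["canonical"], pair_iu["canonical"], loc_iu, "cryptogenic", "uncertain")
    # resolvable homonym: kingdom hint picks the original lineage
    hom = homonyms[0]
    hom_entry = by_name[hom["canonical"]]
    expect_plain(hom_entry, note="Homonym in GBIF")
    mixed_row(hom["canonical"], hom["canonical"], locs[8 % len(locs)], "alien", "introduced",
              kingdom=hom["kingdoms"][0])
    # unresolvable homonym: no hints -> abstains, stays MISSING
    hom2 = homonyms[1]
    expect_missing(hom2["canonical"], note="Homonym in GBIF")
    mixed_row(hom2["canonical"], hom2["canonical"], locs[1], "alien", "introduced")
    # synonym + misspelling via this dialect too
    mixed_row(synonyms[1]["canonical"], expect_synonym(synonyms[1]), locs[2], "indigenous",
              "native")
    mixed_row(
        misspellings[1]["wrong"],
        expect_plain(by_name[misspellings[1]["target"]], verbatim=misspellings[1]["wrong"],
                     match_type="FUZZY"),
        locs[3], "alien", "introduced", year_v="1975", year_e=1975,
    )
    # vagrant record alongside an introduced one for the same taxon+location
    vag = plain[45]
    expect_plain(vag)
    mixed_row(vag["canonical"], vag["canonical"], locs[5], "vagrant (casual)", "vagrant")
    mixed_row(vag["canonical"], vag["canonical"], locs[5], "alien", "introduced")
    # unmatched establishment term: excluded, term reported
    weird = plain[46]
    expect_plain(weird)
    mixed_rows.append(
        {"sciname": weird["canonical"], "author": "", "kingdom": "", "loc": locs[6]["name"],
         "status": "weird-status-xyz", "year_introduced": ""}
    )
    miss("establishmentMeans", "MIXED", "weird-status-xyz")
    exclusions[("MIXED", "establishmentMeans", weird["canonical"],
                "missing establishment after scope inheritance")] = 1
    intents.append(
        _Intent("MIXED", weird["canonical"], weird["canonical"], locs[6]["location_id"],
                locs[6]["name"], None)
    )
    # second unmatched name, native status
    mixed_row(unmatched_names[1], expect_missing(unmatched_names[1]), locs[7], "native",
              "native")
    pd.DataFrame(mixed_rows).to_csv(
        out_dir / "mixed.csv", index=False, lineterminator="\n", encoding="utf-8"
    )

    source_configs = [
        {
            "source_name": "ALIEN-CHK", "citation": citations["ALIEN-CHK"], "scope": "alien",
            "path": str(out_dir / "alien_chk.csv"),
            "column_map": {"taxon": "species", "location": "area", "event_date": "first_record",
                           "occurrence": "presence", "degree": "invasion_degree",
                           "pathway": "introduction_pathway"},
        },
        {
            "source_name": "NATBIN", "citation": citations["NATBIN"], "scope": "mixed",
            "path": str(out_dir / "natbin.csv"),
            "column_map": {"taxon": "name", "location": "region", "establishment": "introduced"},
            "establishment_encoding": {"0": "native", "1": "introduced"},
            "drop_rules": [{"column": "location_doubtful", "values": ["1"]}],
        },
        {
            "source_name": "MULTI", "citation": citations["MULTI"], "scope": "alien",
            "path": str(out_dir / "multi.csv"),
            "column_map": {"taxon": "taxon", "pathway": "pathway", "habitat": "habitat"},
            "location_columns_priority": ["island", "country"],
        },
        {
            "source_name": "RANGES", "citation": citations["RANGES"], "scope": "native",
            "path": str(out_dir / "ranges.geojson"),
            "kind": "range_map", "origin_keep": ["native", "reintroduced"],
        },
        {
            "source_name": "MIXED", "citation": citations["MIXED"], "scope": "mixed",
            "path": str(out_dir / "mixed.csv"),
            "column_map": {"taxon": "sciname", "author": "author", "kingdom": "kingdom",
                           "location": "loc", "establishment": "status",
                           "event_date": "year_introduced"},
        },
    ]

    ledger = _compute_ledger(
        intents, taxa_expect, unmatched_terms, unmatched_locations, exclusions,
        ingest_drops, citations,
    )
    return source_configs, ledger


def _compute_ledger(
    intents: list[_Intent],
    taxa_expect: dict[str, dict],
    unmatched_terms: dict,
    unmatched_locations: dict,
    exclusions: dict,
    ingest_drops: dict,
    citations: dict[str, str],
) -> GroundTruthLedger:
    """Group the planting plan into the expected output tables."""
    # taxa table with IDs: rows sorted by (taxon, verbatim), IDs consecutive
    taxa_rows = sorted(taxa_expect.values(), key=lambda r: (r["taxon"], r["verbatimTaxonRank"]))
    for i, row in enumerate(taxa_rows, start=1):
        row["taxonID"] = str(i)
    taxa_df = pd.DataFrame(taxa_rows, columns=TAXA_COLUMNS)
    first_id: dict[str, str] = {}
    for row in taxa_rows:
        first_id.setdefault(row["taxon"], row["taxonID"])

    habitat_pool: dict[str, set[str]] = {}
    for it in intents:
        if it.location_id is not None and it.establishment and it.habitat:
            habitat_pool.setdefault(it.taxon, set()).update(it.habitat)

    groups: dict[tuple, list[_Intent]] = {}
    for it in intents:
        if it.location_id is None or not it.establishment:
            continue
        bucket = ("alien" if it.establishment in ("introduced", "uncertain")
                  else it.establishment)
        groups.setdefault((it.taxon, it.location_id, bucket), []).append(it)

    rec_rows: list[dict] = []
    for (taxon, loc_id, bucket), members in groups.items():
        kinds = {m.establishment for m in members}
        if kinds == {"introduced", "uncertain"}:
            em = "introduced" + SEP + "uncertain"
        else:
            em = next(iter(kinds))
        introduced_like = em.startswith("introduced")
        years = [m.year for m in members if m.year is not None]
        occ = {m.occurrence for m in members if m.occurrence}
        occurrence = "present" if "present" in occ else ("absent" if occ else "")
        degrees = {m.degree for m in members if m.degree} if introduced_like else set()
        order = ["established", "reproducing", "invasive"]
        degree = max(degrees, key=order.index) if degrees else ""
        pathways = sorted({m.pathway for m in members if m.pathway}) if introduced_like else []
        sources = sorted({m.source for m in members})
        rec_rows.append(
            {
                "location": members[0].location_name,
                "locationID": loc_id,
                "taxon": taxon,
                "taxonID": first_id[taxon],
                "eventDate": "" if not years else str(min(years)),
                "habitat": SEP.join(sorted(habitat_pool.get(taxon, set()))),
                "occurrenceStatus": occurrence,
                "establishmentMeans": em,
                "degreeOfEstablishment": degree,
                "pathway": SEP.join(pathways),
                "datasetName": SEP.join(sources),
                "bibliographicCitation": SEP.join(citations[s] for s in sources),
            }
        )
    rec_rows.sort(key=lambda r: (r["taxon"], r["locationID"], r["establishmentMeans"]))
    for row in rec_rows:
        row["locationID"] = str(row["locationID"])
    records_df = pd.DataFrame(rec_rows, columns=RECORD_COLUMNS)

    unmatched_terms_df = pd.DataFrame(
        [{"field": f, "source": s, "verbatim": v, "count": n}
         for (f, s, v), n in sorted(unmatched_terms.items())],
        columns=["field", "source", "verbatim", "count"],
    )
    unmatched_locations_df = pd.DataFrame(
        [{"source": s, "field": "location", "verbatim": v, "count": n}
         for (s, v), n in sorted(unmatched_locations.items())],
        columns=["source", "field", "verbatim", "count"],
    )
    exclusions_df = pd.DataFrame(
        [{"source": s, "field": f, "verbatim": v, "reason": r, "count": n}
         for (s, f, v, r), n in sorted(exclusions.items())],
        columns=["source", "field", "verbatim", "reason", "count"],
    )

    em_series = [r["establishmentMeans"] for r in rec_rows]
    summary_counts = {
        "n_records": len(rec_rows),
        "n_taxa_total": len(taxa_rows),
        "establishment_counts": {
            em: em_series.count(em) for em in sorted(set(em_series))
        },
        "n_locations": len({r["locationID"] for r in rec_rows}),
        "n_taxa_matched_backbone": sum(
            1 for r in taxa_rows if r["GBIFstatus"] != "MISSING"
        ),
        "coverage_counts": {
            "eventDate": sum(1 for r in rec_rows if r["eventDate"]),
            "occurrenceStatus": sum(1 for r in rec_rows if r["occurrenceStatus"]),
            "degreeOfEstablishment": sum(1 for r in rec_rows if r["degreeOfEstablishment"]),
            "pathway": sum(1 for r in rec_rows if r["pathway"]),
        },
    }
    return GroundTruthLedger(
        records=records_df,
        taxa=taxa_df,
        unmatched_terms=unmatched_terms_df,
        unmatched_locations=unmatched_locations_df,
        exclusions=exclusions_df,
        summary_counts=summary_counts,
        ingest_drops=dict(ingest_drops),
    )


def make_fixture_set(
    dest: str | Path, spec: FixtureSpec | None = None
) -> tuple[Path, GroundTruthLedger]:
    """Generate the complete fixture set and its run configuration.

    Returns the path of the run-config YAML (consumable by
    :func:`sinas.pipeline.run_pipeline` via ``RunConfig.from_file``) and
    the ground-truth ledger.
    """
    spec = spec or FixtureSpec()
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    backbone_path, manifest = generate_backbone(spec, dest)
    geojson_path, table_path, infos = generate_locations(spec, dest)
    source_configs, ledger = generate_sources(spec, manifest, infos, dest)

    config = {
        "output_dir": "output",
        "backbone": {"mode": "fixture", "path": backbone_path.name},
        "locations": {"polygons": geojson_path.name, "translation": table_path.name},
        "sources": [
            {**{k: v for k, v in src.items() if k != "path"}, "path": Path(src["path"]).name}
            for src in source_configs
        ],
    }
    config_path = dest / "run_config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")
    return config_path, ledger
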