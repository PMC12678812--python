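"""Backbone matching cascade: exact, synonym, homonym, fuzzy."""

import pandas as pd
import pytest

from conftest import make_backbone
from sinas.taxon_matcher import (
    LocalBackbone,
    assign_taxa_group,
    build_taxa_list,
    damerau_levenshtein,
    match_taxon,
    resolve_homonym,
    strip_authority,
)

ANIMAL = {"kingdom": "Animalia", "phylum": "Chordata", "class": "Aves",
          "order": "Passeriformes", "family": "Estrildidae", "genus": "Lonchura"}
PLANT = {"kingdom": "Plantae", "phylum": "Tracheophyta", "class": "Magnoliopsida",
         "order": "Asterales", "family": "Asteraceae", "genus": "Abea"}


@pytest.fixture(scope="module")
def backbone():
    return make_backbone([
        (1, "Lonchura malacca", "(Linnaeus, 1766)", "ACCEPTED", 1,
         {**ANIMAL, "species": "Lonchura malacca"}),
        (2, "Abea beota", "Mill.", "ACCEPTED", 2, {**PLANT, "species": "Abea beota"}),
        (3, "Abea vetusta", "L.", "SYNONYM", 2, {**PLANT, "species": "Abea beota"}),
        # homonym pair: same canonical, different kingdoms
        (4, "Dorin parva", "(Corvan, 1820)", "ACCEPTED", 4,
         {**ANIMAL, "species": "Dorin parva"}),
        (5, "Dorin parva", "Fenor", "ACCEPTED", 5, {**PLANT, "species": "Dorin parva"}),
        # a name at distance 1 from an accepted name AND itself accepted:
        # exact must always beat fuzzy
        (6, "Cusa dilo", "Brel", "ACCEPTED", 6, {**PLANT, "species": "Cusa dilo"}),
        (7, "Cusa dila", "Brel", "ACCEPTED", 7, {**PLANT, "species": "Cusa dila"}),
        # isolated name for clean fuzzy tests
        (8, "Vastinor grandiflora", "Harst", "ACCEPTED", 8,
         {**PLANT, "species": "Vastinor grandiflora"}),
    ])


class TestCascade:
    def test_exact_accepted_match(self, backbone):
        match = match_taxon("Lonchura malacca", backbone, {"kingdom": "Animalia"})
        assert match.status == "ACCEPTED"
        assert match.match_type == "EXACT"
        assert match.usage_key == 1
        assert match.higher["family"] == "Estrildidae"
        assert match.taxa_group == "Birds"

    def test_synonym_replaced_by_accepted_name_and_flagged(self, backbone):
        match = match_taxon("Abea vetusta", backbone)
        assert match.status == "SYNONYM"
        assert match.taxon == "Abea beota"
        assert match.usage_key == 2
        assert match.status_synonym == "ACCEPTED"
        assert match.note == "Accepted name found on GBIF"

    def test_exact_beats_fuzzy(self, backbone):
        # 'Cusa dila' is one edit from 'Cusa dilo' but has its own entry
        match = match_taxon("Cusa dila", backbone)
        assert (match.match_type, match.usage_key) == ("EXACT", 7)

    def test_fuzzy_sole_candidate_at_full_confidence(self, backbone):
        match = match_taxon("Vastinor grandiflora".replace("flora", "flora")[:-1] + "e",
                            backbone)
        assert match.status == "ACCEPTED"
        assert match.match_type == "FUZZY"
        assert match.taxon == "Vastinor grandiflora"

    def test_fuzzy_rejected_when_confidence_below_100(self, backbone):
        # 'Cusa dilu' is distance 1 from both 'Cusa dilo' and 'Cusa dila':
        # no sole candidate, so confidence never reaches 100
        match = match_taxon("Cusa dilu", backbone)
        assert match.status == "MISSING"
        assert match.taxon == "Cusa dilu"

    def test_two_edits_away_is_missing(self, backbone):
        match = match_taxon("Vastinor grandifluri", backbone)
        assert match.status == "MISSING"

    def test_unmatched_name_keeps_verbatim_and_no_backbone_fields(self, backbone):
        match = match_taxon("Nullius nomen", backbone)
        assert match.status == "MISSING"
        assert match.taxon == "Nullius nomen"
        assert match.usage_key is None and match.higher == {}

    def test_hybrid_marker_stripped_for_matching(self, backbone):
        match = match_taxon("Abea × beota", backbone)
        assert match.usage_key == 2

    def test_empty_name_rejected(self, backbone):
        with pytest.raises(ValueError):
            match_taxon("  ", backbone)

    def test_determinism_independent_of_record_order(self, backbone):
        names = ["Abea vetusta", "Cusa dila", "Dorin parva", "Lonchura malacca"]
        first = [match_taxon(n, backbone) for n in names]
        second = [match_taxon(n, backbone) for n in reversed(names)]
        assert first == list(reversed(second))


class TestHomonyms:
    def test_kingdom_hint_resolves(self, backbone):
        match = match_taxon("Dorin parva", backbone, {"kingdom": "Plantae"})
        assert match.usage_key == 5
        assert match.note == "Homonym in GBIF"

    def test_no_hints_abstains_with_flag(self, backbone):
        match = match_taxon("Dorin parva", backbone)
        assert match.status == "MISSING"
        assert match.note == "Homonym in GBIF"
        assert match.usage_key is None

    def test_author_hint_applied_before_kingdom(self, backbone):
        entries = backbone.lookup_exact("Dorin parva")
        chosen = resolve_homonym(entries, {"author": "Fenor", "kingdom": "Animalia"})
        assert chosen.usage_key == 5  # author hint wins; kingdom never consulted

    def test_three_candidates_author_hint(self):
        entries = make_backbone([
            (1, "Trex una", "Brel", "ACCEPTED", 1, {**PLANT, "species": "Trex una"}),
            (2, "Trex una", "Corvan", "ACCEPTED", 2, {**ANIMAL, "species": "Trex una"}),
            (3, "Trex una", "Harst", "ACCEPTED", 3, {**PLANT, "species": "Trex una"}),
        ]).lookup_exact("Trex una")
        assert resolve_homonym(entries, {"author": "Corvan"}).usage_key == 2
        assert resolve_homonym(entries, {}) is None


class TestStripAuthority:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Lonchura malacca (Linnaeus, 1766)", "Lonchura malacca"),
            ("Lonchura malacca", "Lonchura malacca"),
            ("Abies alba Mill.", "Abies alba"),
            ("Poa annua var. annua L.", "Poa annua var. annua"),
            ("Abea beota subsp. minor (Brel, 1900)", "Abea beota subsp. minor"),
        ],
    )
    def test_authority_removed_markers_kept(self, name, expected):
        assert strip_authority(name) == expected

    def test_agrees_with_backbone_canonical(self, backbone):
        for entry in backbone.lookup_exact("Lonchura malacca"):
            assert strip_authority(entry.scientific_name) == entry.canonical_name


class TestTaxaGroups:
    @pytest.mark.parametrize(
        "higher,expected",
        [
            ({"class": "Aves"}, "Birds"),
            ({"kingdom": "Fungi"}, "Fungi"),
            ({"phylum": "Tracheophyta", "kingdom": "Plantae"}, "Vascular plants"),
            ({"class": "Insecta", "phylum": "Arthropoda"}, "Insects"),
            ({"phylum": "Arthropoda", "class": "Diplopoda"}, "Other arthropods"),
            ({"kingdom": "Chromista", "phylum": "Ochrophyta"}, "SAR"),
            ({"kingdom": "Animalia", "phylum": "Cnidaria"}, "Other aquatic animals"),
            ({}, None),
        ],
    )
    def test_first_matching_rule_wins(self, higher, expected):
        assert assign_taxa_group(higher) == expected

    def test_unknown_rank_in_rule_is_config_error(self):
        with pytest.raises(ValueError, match="unknown rank"):
            assign_taxa_group({"class": "Aves"}, [("tribus", "X", "Y")])


class TestBuildTaxaList:
    def test_synonym_pair_shares_taxon_distinct_verbatim(self, backbone):
        matches = [match_taxon("Abea beota", backbone), match_taxon("Abea vetusta", backbone)]
        table = build_taxa_list(matches)
        assert list(table["taxon"]) == ["Abea beota", "Abea beota"]
        assert list(table["verbatimTaxonRank"]) == ["Abea beota", "Abea vetusta"]

    def test_missing_taxon_row_has_empty_taxonomy(self, backbone):
        table = build_taxa_list([match_taxon("Nullius nomen", backbone)])
        row = table.iloc[0]
        assert row["GBIFstatus"] == "MISSING"
        assert row["kingdom"] == "" and row["GBIFusageKey"] == ""

    def test_empty_match_set(self):
        assert len(build_taxa_list([])) == 0


def _osa_distance(a, b):
    """Independent optimal-string-alignment distance (full DP, no cutoff)."""
    d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        d[i][0] = i
    for j in range(len(b) + 1):
        d[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[len(a)][len(b)]


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("abc", "abc", 0), ("abc", "abd", 1), ("abc", "acb", 1), ("abc", "xyz", 3),
         ("abcd", "ab", 2), ("", "ab", 2)],
    )
    def test_known_distances(self, a, b, expected):
        assert damerau_levenshtein(a, b) == min(expected, 3)

    def test_matches_full_dp_oracle(self):
        words = ["vastinor", "vastinar", "vastinro", "cusa", "cusad", "xy"]
        for a in words:
            for b in words:
                assert damerau_levenshtein(a, b, cutoff=3) == min(_osa_distance(a, b), 3)


class TestFixtureBackboneOracle:
    def test_match_agrees_with_brute_force_scan(self, tmp_path):
        """On the generated fixture backbone, the cascade agrees with a
        brute-force oracle scanning every row under the same normalization
        and edit-distance rule."""
        from sinas.fixtures import FixtureSpec, generate_backbone

        path, manifest = generate_backbone(FixtureSpec(seed=7, n_true_taxa=30), tmp_path)
        backbone = LocalBackbone.from_file(path)
        table = pd.read_csv(path, dtype=str)

        queries = (
            [a["canonical"] for a in manifest["accepted"][:10]]
            + [s["canonical"] for s in manifest["synonyms"]]
            + [m["wrong"] for m in manifest["misspellings"]]
            + manifest["unmatched"]
        )
        for query in queries:
            exact_rows = table[table["canonical_name"].str.lower() == query.lower()]
            if len(exact_rows) == 1:
                row = exact_rows.iloc[0]
                expected = (
                    table.set_index("usage_key").loc[row["accepted_usage_key"],
                                                     "canonical_name"]
                    if row["status"] == "SYNONYM"
                    else row["canonical_name"]
                )
            elif len(exact_rows) > 1:
                expected = query  # unresolved homonym abstains
            else:
                d1 = [
                    r for _, r in table.iterrows()
                    if _osa_distance(query.lower(), r["canonical_name"].lower()) == 1
                ]
                d2 = [
                    r for _, r in table.iterrows()
                    if _osa_distance(query.lower(), r["canonical_name"].lower()) == 2
                ]
                expected = d1[0]["canonical_name"] if len(d1) == 1 and not d2 else query
            assert match_taxon(query, backbone).taxon == expected, query
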