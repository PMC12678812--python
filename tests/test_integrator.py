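"""Merge semantics, identifier assignment, summary statistics, output files."""

import random

import pandas as pd
import pytest

from sinas.data_model import RECORD_COLUMNS, TAXA_COLUMNS, read_table
from sinas.integrator import (
    StandardizedRecord,
    assign_ids,
    merge_records,
    percentage,
    summarize_dataset,
    write_outputs,
)

CITATIONS = {"A": "Cite A", "B": "Cite B", "C": "Cite C"}


def rec(taxon="X", loc=1, est="introduced", source="A", year=None, occ=None,
        degree=None, pathway=None, habitat=""):
    return StandardizedRecord(
        source_name=source, taxon=taxon, location_verbatim=f"L{loc}", location_id=loc,
        location_name=f"L{loc}", establishment=est, occurrence=occ, degree=degree,
        pathway=pathway, habitat=habitat, year=year,
    )


class TestMergeRecords:
    def test_introduced_and_uncertain_concatenate(self):
        result = merge_records(
            [rec(est="introduced", year=1950, source="A"),
             rec(est="uncertain", source="B")],
            CITATIONS,
        )
        assert len(result.records) == 1
        row = result.records.iloc[0]
        assert row["establishmentMeans"] == "introduced; uncertain"
        assert row["eventDate"] == 1950
        assert row["datasetName"] == "A; B"
        assert row["bibliographicCitation"] == "Cite A; Cite B"

    def test_uncertain_alone_stays_uncertain(self):
        result = merge_records([rec(est="uncertain")], CITATIONS)
        assert result.records.iloc[0]["establishmentMeans"] == "uncertain"

    def test_duplicates_keep_earliest_year(self):
        result = merge_records(
            [rec(year=1950), rec(year=1903)], CITATIONS,
        )
        assert len(result.records) == 1
        assert result.records.iloc[0]["eventDate"] == 1903

    def test_native_and_introduced_stay_separate(self):
        result = merge_records([rec(est="native"), rec(est="introduced")], CITATIONS)
        assert sorted(result.records["establishmentMeans"]) == ["introduced", "native"]

    def test_vagrant_kept_separate_from_alien_class(self):
        result = merge_records(
            [rec(est="vagrant"), rec(est="introduced"), rec(est="uncertain")], CITATIONS
        )
        assert sorted(result.records["establishmentMeans"]) == [
            "introduced; uncertain", "vagrant",
        ]

    def test_present_beats_absent_and_conflict_logged(self):
        result = merge_records(
            [rec(occ="present"), rec(occ="absent", source="B")], CITATIONS
        )
        assert result.records.iloc[0]["occurrenceStatus"] == "present"
        assert len(result.conflicts) == 1

    def test_degree_and_pathway_only_on_introduced_like(self):
        result = merge_records(
            [rec(est="native", degree="established", pathway="corridor")], CITATIONS
        )
        row = result.records.iloc[0]
        assert row["degreeOfEstablishment"] == "" and row["pathway"] == ""

    def test_pathways_joined_sorted_unique(self):
        result = merge_records(
            [rec(pathway="corridor"), rec(pathway="unaided", source="B"),
             rec(pathway="corridor", source="C")],
            CITATIONS,
        )
        assert result.records.iloc[0]["pathway"] == "corridor; unaided"

    def test_habitat_pools_per_taxon_across_locations(self):
        result = merge_records(
            [rec(loc=1, habitat="marine"), rec(loc=2, habitat="terrestrial")], CITATIONS
        )
        assert set(result.records["habitat"]) == {"marine; terrestrial"}

    def test_unmatched_location_routed_to_exclusions(self):
        bad = StandardizedRecord(
            source_name="A", taxon="X", location_verbatim="Atlantis", location_id=None,
            location_name=None, establishment="introduced",
        )
        result = merge_records([bad, rec()], CITATIONS)
        assert len(result.records) == 1
        assert result.exclusions.iloc[0]["verbatim"] == "Atlantis"

    def test_count_conservation(self):
        records = [rec(taxon=f"T{i % 5}", loc=i % 3, est=e, source=s)
                   for i, (e, s) in enumerate(
                       [("introduced", "A"), ("native", "B"), ("uncertain", "A")] * 7)]
        records.append(StandardizedRecord("A", "T0", "bad", None, None, "introduced"))
        result = merge_records(records, CITATIONS)
        excluded = int(result.exclusions["count"].sum())
        group_sizes = len(records) - excluded
        # every input record lands in exactly one merge group or one exclusion
        assert excluded == 1
        regrouped = {}
        for r in records[:-1]:
            bucket = "alien" if r.establishment in ("introduced", "uncertain") else r.establishment
            regrouped.setdefault((r.taxon, r.location_id, bucket), []).append(r)
        assert sum(len(v) for v in regrouped.values()) == group_sizes
        assert len(result.records) == len(regrouped)

    def test_order_invariance(self):
        records = [rec(taxon=f"T{i % 4}", loc=i % 3, est=e, source=s, year=1900 + i)
                   for i, (e, s) in enumerate(
                       [("introduced", "A"), ("native", "B"), ("uncertain", "C")] * 5)]
        base = merge_records(records, CITATIONS).records
        rng = random.Random(0)
        for _ in range(3):
            shuffled = records[:]
            rng.shuffle(shuffled)
            pd.testing.assert_frame_equal(merge_records(shuffled, CITATIONS).records, base)

    def test_merge_is_idempotent_on_its_own_output(self):
        records = [
            rec(est="introduced", year=1950, occ="present", degree="established",
                pathway="corridor"),
            rec(est="uncertain", source="B"),
            rec(est="native", source="B"),
            rec(taxon="Y", loc=2, est="vagrant"),
        ]
        first = merge_records(records, CITATIONS).records
        fed_back = []
        citations = {}
        for _, row in first.iterrows():
            citations[row["datasetName"]] = row["bibliographicCitation"]
            fed_back.append(
                StandardizedRecord(
                    source_name=row["datasetName"], taxon=row["taxon"],
                    location_verbatim=row["location"], location_id=row["locationID"],
                    location_name=row["location"],
                    establishment=row["establishmentMeans"],
                    occurrence=row["occurrenceStatus"] or None,
                    degree=row["degreeOfEstablishment"] or None,
                    pathway=row["pathway"] or None, habitat=row["habitat"],
                    year=None if row["eventDate"] == "" else int(row["eventDate"]),
                )
            )
        second = merge_records(fed_back, citations).records
        pd.testing.assert_frame_equal(second, first)


class TestAssignIds:
    def _taxa(self, names):
        rows = []
        for verbatim, taxon in names:
            row = {c: "" for c in TAXA_COLUMNS if c != "taxonID"}
            row.update(verbatimTaxonRank=verbatim, taxon=taxon, GBIFstatus="ACCEPTED")
            rows.append(row)
        return pd.DataFrame(rows)

    def test_ids_consecutive_over_sorted_taxa_and_stable(self):
        taxa = self._taxa([("B b", "B b"), ("A a", "A a"), ("A syn", "A a")])
        records = pd.DataFrame(
            [{"location": "L", "locationID": 1, "taxon": "A a", "eventDate": "",
              "habitat": "", "occurrenceStatus": "", "establishmentMeans": "native",
              "degreeOfEstablishment": "", "pathway": "", "datasetName": "A",
              "bibliographicCitation": "Cite A"}]
        )
        rec1, tax1 = assign_ids(records, taxa)
        assert list(tax1["taxonID"]) == [1, 2, 3]
        assert list(tax1["verbatimTaxonRank"]) == ["A a", "A syn", "B b"]
        # record carries the first taxa row sharing its accepted taxon
        assert rec1.iloc[0]["taxonID"] == 1
        rec2, tax2 = assign_ids(records, taxa)
        pd.testing.assert_frame_equal(tax1, tax2)

    def test_appending_lexicographically_last_taxon_preserves_ids(self):
        base = self._taxa([("A a", "A a"), ("B b", "B b")])
        extended = self._taxa([("A a", "A a"), ("B b", "B b"), ("Zz z", "Zz z")])
        empty = pd.DataFrame(columns=[c for c in RECORD_COLUMNS if c != "taxonID"])
        _, tax_base = assign_ids(empty, base)
        _, tax_ext = assign_ids(empty, extended)
        merged = tax_ext.set_index("verbatimTaxonRank")["taxonID"]
        for _, row in tax_base.iterrows():
            assert merged[row["verbatimTaxonRank"]] == row["taxonID"]


class TestSummary:
    def test_small_dataset_shares(self):
        records = pd.DataFrame(
            [{"location": "L", "locationID": 1, "taxon": f"T{i}", "taxonID": i + 1,
              "eventDate": "", "habitat": "", "occurrenceStatus": "",
              "establishmentMeans": "introduced" if i < 4 else "native",
              "degreeOfEstablishment": "", "pathway": "", "datasetName": "A",
              "bibliographicCitation": "Cite A"} for i in range(10)]
        )
        taxa = pd.DataFrame(
            [{c: "" for c in TAXA_COLUMNS} | {"taxon": f"T{i}", "taxonID": str(i + 1),
                                              "GBIFstatus": "ACCEPTED"}
             for i in range(10)]
        )
        summary = summarize_dataset(records, taxa)
        assert summary.establishment_pct["introduced"] == 40.0
        assert summary.establishment_pct["native"] == 60.0
        assert summary.n_taxa_alien_distribution == 4

    def test_empty_dataset_has_absent_percentages(self):
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        taxa = pd.DataFrame(columns=TAXA_COLUMNS)
        summary = summarize_dataset(records, taxa)
        assert summary.n_records == 0
        assert summary.pct_taxa_matched_backbone is None

    @pytest.mark.parametrize(
        "count,denom,expected",
        [(4, 10, 40.0), (1, 3, 33.3), (2, 3, 66.7), (1, 800, 0.1), (5, 1000, 0.5),
         (0, 7, 0.0), (1, 0, None)],
    )
    def test_percentage_round_half_up_one_decimal(self, count, denom, expected):
        assert percentage(count, denom) == expected


class TestWriteOutputs:
    def _tables(self):
        records = pd.DataFrame(
            [{"location": "L", "locationID": "1", "taxon": "T", "taxonID": "1",
              "eventDate": "", "habitat": "", "occurrenceStatus": "",
              "establishmentMeans": "native", "degreeOfEstablishment": "", "pathway": "",
              "datasetName": "A", "bibliographicCitation": "Cite A"}]
        )
        taxa = pd.DataFrame(
            [{c: "" for c in TAXA_COLUMNS} | {"taxon": "T", "verbatimTaxonRank": "T",
                                              "taxonID": "1", "GBIFstatus": "MISSING"}]
        )
        reports = {
            "unmatched_terms": pd.DataFrame(
                [{"field": "pathway", "source": "A", "verbatim": "odd", "count": 1}]
            ),
            "unmatched_locations": pd.DataFrame(
                [{"source": "A", "field": "location", "verbatim": "Atlantis", "count": 1}]
            ),
            "exclusions": pd.DataFrame(
                columns=["source", "field", "verbatim", "reason", "count"]
            ),
        }
        return records, taxa, reports

    def test_file_set_and_byte_identical_rerun(self, tmp_path):
        records, taxa, reports = self._tables()
        written = write_outputs(records, taxa, reports, tmp_path)
        assert written["records"].exists() and written["taxa"].exists()
        assert len([p for p in written.values() if p.suffix == ".csv"]) >= 5
        first = {name: p.read_bytes() for name, p in written.items()}
        written2 = write_outputs(records, taxa, reports, tmp_path)
        assert {name: p.read_bytes() for name, p in written2.items()} == first

    def test_unmatched_location_appears_once_with_count(self, tmp_path):
        records, taxa, reports = self._tables()
        written = write_outputs(records, taxa, reports, tmp_path)
        table = read_table(written["unmatched_locations"])
        assert list(table["verbatim"]) == ["Atlantis"]
        assert list(table["count"]) == ["1"]
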