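"""Tests for normalization, validation and deduplication."""
import datetime as dt

import pytest

import pvsignal as pv
from pvsignal import study
from pvsignal.curation import (
    ParseError,
    REASON_DATE,
    REASON_DEMOGRAPHICS,
    REASON_DRUGS,
    REASON_REACTIONS,
    SynonymMap,
    curate,
    deduplicate,
    normalize_drug_names,
    read_report_tables,
    validate_records,
)
from conftest import make_report

WINDOW = (dt.date(2003, 12, 1), dt.date(2024, 12, 31))


def raw_report(rid, verbatims, reactions, **kwargs):
    rec = make_report(rid, [(v, r) for v, r in verbatims], reactions, **kwargs)
    for e in rec.drugs:  # undo conftest's pre-normalization
        e.normalized_name = None
    return rec


class TestSynonymMap:
    def test_brand_maps_to_canonical(self):
        m = SynonymMap.from_pairs([("ozempic", "semaglutide"), ("semaglutide", "semaglutide")])
        assert m.lookup("OZEMPIC") == ("semaglutide", True)

    def test_canonical_self_maps(self):
        m = SynonymMap.from_pairs([("Lithobid", "lithium")])
        assert m.lookup("lithium") == ("lithium", True)

    def test_miss_is_flagged_not_fatal(self):
        m = SynonymMap.from_pairs([("lithobid", "lithium")])
        assert m.lookup("xyzzy-999") == ("xyzzy-999", False)

    def test_non_functional_map_rejected(self):
        with pytest.raises(ParseError, match="not functional"):
            SynonymMap.from_pairs([("advil", "ibuprofen"), ("ADVIL", "naproxen")])


class TestNormalization:
    def test_mapping_and_idempotence(self):
        records = [raw_report("r1", [("OZEMPIC", "PS")], {"Nausea"})]
        m = SynonymMap.from_pairs([("ozempic", "semaglutide")])
        normalize_drug_names(records, m)
        entry = records[0].drugs[0]
        assert (entry.normalized_name, entry.unresolved) == ("semaglutide", False)
        normalize_drug_names(records, m)  # second pass changes nothing
        assert (entry.normalized_name, entry.unresolved) == ("semaglutide", False)

    def test_unresolved_names_are_kept(self):
        records = [raw_report("r1", [("xyzzy-999", "PS")], {"Nausea"})]
        normalize_drug_names(records, SynonymMap.from_pairs([("a", "a")]))
        entry = records[0].drugs[0]
        assert (entry.normalized_name, entry.unresolved) == ("xyzzy-999", True)


class TestValidation:
    def test_reason_precedence_and_tallies(self):
        records = [
            make_report("r1", [("lithium", "PS")], {"Nausea"}),  # valid
            make_report("r2", [("lithium", "PS")], set()),  # no reactions
            make_report("r3", [], {"Nausea"}),  # no drugs
            make_report("r4", [("lithium", "PS")], {"Nausea"}, age=-3.0),
            make_report("r5", [], set(), date=dt.date(2002, 5, 1)),  # date wins
            make_report("r6", [("lithium", "PS")], {"Nausea"}, date=None),
        ]
        kept, report = validate_records(records, WINDOW)
        assert [r.report_id for r in kept] == ["r1"]
        assert report.exclusion_reasons == {
            REASON_REACTIONS: 1, REASON_DRUGS: 1, REASON_DEMOGRAPHICS: 1, REASON_DATE: 2,
        }
        assert report.n_input == 6 and report.n_output == 1

    def test_window_is_closed(self):
        edge_lo = make_report("r1", [("a", "PS")], {"x"}, date=WINDOW[0])
        edge_hi = make_report("r2", [("a", "PS")], {"x"}, date=WINDOW[1])
        outside = make_report("r3", [("a", "PS")], {"x"}, date=dt.date(2025, 1, 1))
        kept, _ = validate_records([edge_lo, edge_hi, outside], WINDOW)
        assert [r.report_id for r in kept] == ["r1", "r2"]

    def test_missing_age_is_allowed(self):
        rec = make_report("r1", [("a", "PS")], {"x"}, age=None)
        kept, _ = validate_records([rec], WINDOW)
        assert kept == [rec]


class TestDeduplication:
    def test_latest_date_kept(self):
        early = make_report("r1", [("lithium", "PS")], {"Nausea"}, date=dt.date(2020, 1, 1))
        late = make_report("r2", [("lithium", "PS")], {"Nausea"}, date=dt.date(2020, 1, 15))
        kept, report = deduplicate([early, late])
        assert [r.report_id for r in kept] == ["r2"]
        assert report.n_removed_duplicates == 1

    def test_date_tie_broken_by_smallest_id(self):
        a = make_report("r9", [("lithium", "PS")], {"Nausea"})
        b = make_report("r2", [("lithium", "PS")], {"Nausea"})
        kept, _ = deduplicate([a, b])
        assert [r.report_id for r in kept] == ["r2"]

    def test_differing_reaction_sets_are_distinct(self):
        a = make_report("r1", [("lithium", "PS")], {"Nausea"})
        b = make_report("r2", [("lithium", "PS")], {"Nausea", "Rash"})
        kept, _ = deduplicate([a, b])
        assert len(kept) == 2

    def test_shared_case_id_groups_despite_field_changes(self):
        v1 = make_report("r1", [("lithium", "PS")], {"Nausea"}, case_id="case-X",
                         date=dt.date(2020, 1, 1))
        v2 = make_report("r2", [("lithium", "PS")], {"Nausea", "Tremor"}, case_id="case-X",
                         date=dt.date(2020, 3, 1))
        kept, _ = deduplicate([v1, v2])
        assert [r.report_id for r in kept] == ["r2"]

    def test_age_rounded_in_key(self):
        a = make_report("r1", [("lithium", "PS")], {"Nausea"}, age=50.2)
        b = make_report("r2", [("lithium", "PS")], {"Nausea"}, age=50.0)
        kept, _ = deduplicate([a, b])
        assert len(kept) == 1

    def test_order_invariance(self):
        records = [
            make_report(f"r{i}", [("lithium", "PS")], {"Nausea"}, date=dt.date(2020, 1, 1 + i))
            for i in range(5)
        ] + [make_report("q1", [("metformin", "PS")], {"Rash"})]
        kept_fwd, _ = deduplicate(list(records))
        kept_rev, _ = deduplicate(records[::-1])
        assert {r.report_id for r in kept_fwd} == {r.report_id for r in kept_rev}


class TestChainOnSyntheticData:
    def test_conservation_and_clone_recall(self):
        config = study.default_sim_config(
            n_reports=2000, seed=5, duplicate_rate=0.025, invalid_rate=0.02
        )
        reports, truth = pv.generate_reports(config)
        assert len(truth.duplicate_of) == 50
        curated, report = curate(reports, study.default_synonym_map(), study.WINDOW)
        assert report.n_input == report.n_output + report.n_excluded_invalid + report.n_removed_duplicates
        kept_ids = {r.report_id for r in curated}
        # every injected clone pair collapsed to a single surviving record
        for clone, src in truth.duplicate_of.items():
            assert (clone in kept_ids) + (src in kept_ids) == 1

    def test_no_false_positive_removals_on_clean_database(self):
        config = study.default_sim_config(
            n_reports=5000, seed=6, duplicate_rate=0.0, invalid_rate=0.0
        )
        reports, _ = pv.generate_reports(config)
        curated, report = curate(reports, study.default_synonym_map(), study.WINDOW)
        # any removal on a clone-free database must be a genuine key collision
        from pvsignal.curation import _duplicate_key

        kept_ids = {r.report_id for r in curated}
        keys = {}
        for r in reports:
            keys.setdefault(_duplicate_key(r), []).append(r.report_id)
        colliding = {rid for ids in keys.values() if len(ids) > 1 for rid in ids}
        removed = {r.report_id for r in reports} - kept_ids
        assert removed <= colliding

    def test_idempotence(self):
        config = study.default_sim_config(
            n_reports=2000, seed=9, duplicate_rate=0.05, invalid_rate=0.03
        )
        reports, _ = pv.generate_reports(config)
        synonyms = study.default_synonym_map()
        once, rep1 = curate(reports, synonyms, study.WINDOW)
        twice, rep2 = curate(list(once), synonyms, study.WINDOW)
        assert twice == once
        assert rep2.n_excluded_invalid == 0 and rep2.n_removed_duplicates == 0


class TestReader:
    def test_duplicate_report_id_rejected(self, tmp_path):
        reports, _ = pv.generate_reports(
            study.default_sim_config(n_reports=5, seed=1, duplicate_rate=0, invalid_rate=0)
        )
        pv.write_report_tables(reports, tmp_path)
        demo = tmp_path / "demo.csv"
        lines = demo.read_text().splitlines()
        demo.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(ParseError, match="duplicate report_id"):
            read_report_tables(tmp_path)

    def test_missing_table_rejected(self, tmp_path):
        (tmp_path / "demo.csv").write_text("report_id,case_id,receipt_date,age_years,sex,country\n")
        with pytest.raises(ParseError, match="missing table"):
            read_report_tables(tmp_path)

    def test_orphan_drug_row_rejected(self, tmp_path):
        reports, _ = pv.generate_reports(
            study.default_sim_config(n_reports=5, seed=1, duplicate_rate=0, invalid_rate=0)
        )
        pv.write_report_tables(reports, tmp_path)
        with open(tmp_path / "drug.csv", "a") as f:
            f.write("R99999999,mystery,PS\n")
        with pytest.raises(ParseError, match="absent from demo"):
            read_report_tables(tmp_path)

    def test_demo_only_report_gets_empty_lists(self, tmp_path):
        (tmp_path / "demo.csv").write_text(
            "report_id,case_id,receipt_date,age_years,sex,country\n"
            "r1,c1,2020-01-01,50,F,US\n"
        )
        (tmp_path / "drug.csv").write_text("report_id,verbatim_name,role\n")
        (tmp_path / "reac.csv").write_text("report_id,preferred_term\n")
        records = read_report_tables(tmp_path)
        assert records[0].drugs == [] and records[0].reactions == frozenset()

    def test_bad_role_rejected(self, tmp_path):
        (tmp_path / "demo.csv").write_text(
            "report_id,case_id,receipt_date,age_years,sex,country\n"
            "r1,c1,2020-01-01,50,F,US\n"
        )
        (tmp_path / "drug.csv").write_text("report_id,verbatim_name,role\nr1,advil,XX\n")
        (tmp_path / "reac.csv").write_text("report_id,preferred_term\nr1,Nausea\n")
        with pytest.raises(ParseError, match="unknown role"):
            read_report_tables(tmp_path)
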