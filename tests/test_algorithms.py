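"""Clinical screening algorithms: ranking, profile comparison, DDI,
background correction and the confounder screen."""

from __future__ import annotations

import random

import pytest

from pvsignal import (
    PlantedAssociation,
    PlantedConfounder,
    PlantedInteraction,
    Query,
    ReportStore,
    SafetyReport,
    SyntheticConfig,
    analyze_pair,
    background_corrected,
    compare_drug_profiles,
    confounder_screen,
    ddi_screen,
    fixture_model_case,
    generate,
    rank_drugs_for_event,
    rrr_perc_diff,
)

from conftest import make_random_store


class TestRanking:
    def test_single_drug_reproduces_pairwise_analysis(self):
        store = fixture_model_case(1)
        ranking = rank_drugs_for_event(store, ["DRUGX"], "EVENTY")
        pair = analyze_pair(store, "DRUGX", "EVENTY")
        (entry,) = ranking.entries
        assert entry.rrr == pair.rrr == pytest.approx(1.0)
        assert (entry.DE, entry.D, entry.rate) == (
            pair.table.DE, pair.table.D, pair.rate,
        )

    def test_planted_association_ranks_first(self):
        config = SyntheticConfig(
            n_reports=30_000,
            drug_vocab=(("DRUGA", 0.02), ("DRUGB", 0.02)),
            event_vocab=(("EVENTY", 0.02),),
            associations=(PlantedAssociation("DRUGA", "EVENTY", 5.0),),
            seed=101,
        )
        ranking = rank_drugs_for_event(generate(config), ["DRUGB", "DRUGA"], "EVENTY")
        assert ranking.entries[0].drug == "DRUGA"
        assert ranking.entries[0].rrr > ranking.entries[1].rrr

    def test_absent_drug_ranks_last_with_undefined_rrr(self):
        store = fixture_model_case(2)
        ranking = rank_drugs_for_event(store, ["DRUGX", "GHOSTDRUG"], "EVENTY")
        last = ranking.entries[-1]
        assert last.drug == "GHOSTDRUG"
        assert (last.DE, last.D) == (0, 0)
        assert last.rrr is None and last.rate is None

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError, match="at least one drug"):
            rank_drugs_for_event(ReportStore(), [], "EVENTY")


class TestPercDiff:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (1.0, 2.0, -200 / 3),       # a meaningful difference
            (100.0, 101.0, -0.995_024_875_621_89),  # probably chance
            (3.0, 3.0, 0.0),
            (5.0, 0.0, 200.0),          # formula limit when one RRR is 0
            (0.0, 5.0, -200.0),
        ],
    )
    def test_values(self, r1, r2, expected):
        assert rrr_perc_diff(r1, r2) == pytest.approx(expected)

    def test_undefined_cases(self):
        assert rrr_perc_diff(0.0, 0.0) is None
        assert rrr_perc_diff(None, 2.0) is None
        assert rrr_perc_diff(2.0, None) is None

    def test_bounded_and_antisymmetric(self):
        rng = random.Random(2)
        for _ in range(200):
            r1 = rng.uniform(0, 50)
            r2 = rng.uniform(0, 50)
            pd = rrr_perc_diff(r1, r2)
            assert -200.0 <= pd <= 200.0
            assert pd == pytest.approx(-rrr_perc_diff(r2, r1))


def _profile_store() -> ReportStore:
    """Deterministic store where two drugs share events at different strengths."""
    reports = []

    def emit(n, drugs, reactions):
        for _ in range(n):
            reports.append(SafetyReport(
                f"P{len(reports):04d}", drugs=frozenset(drugs),
                reactions=frozenset(reactions)))

    emit(30, {"ALPHADRUG"}, {"RASH"})
    emit(10, {"ALPHADRUG"}, {"NAUSEA"})
    emit(3, {"ALPHADRUG"}, {"DIZZINESS"})
    emit(10, {"BETADRUG"}, {"RASH"})
    emit(30, {"BETADRUG"}, {"NAUSEA"})
    emit(3, {"BETADRUG"}, {"DIZZINESS"})
    emit(5, {"ALPHADRUG", "BETADRUG"}, {"HEADACHE"})   # combination reports
    emit(115, {"OTHERDRUG"}, {"OTHEREVENT"})
    return ReportStore(reports)


class TestProfileComparison:
    def test_identical_drugs_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            compare_drug_profiles(ReportStore(), "x", "X ")

    def test_combination_reports_excluded_from_both_populations(self):
        store = _profile_store()
        cmp_ = compare_drug_profiles(store, "ALPHADRUG", "BETADRUG", include_all=True)
        assert cmp_.d1_total == 43 and cmp_.d2_total == 43 and cmp_.combo_total == 5
        # conservation: exclusive populations + combination + neither = N
        neither = store.count(Query(drug_none=frozenset({"ALPHADRUG", "BETADRUG"})))
        assert cmp_.d1_total + cmp_.d2_total + cmp_.combo_total + neither == len(store)
        # HEADACHE occurs only in combination reports, so it is outside the
        # combination-excluded event universe entirely
        assert {r.event for r in cmp_.rows} == {"RASH", "NAUSEA", "DIZZINESS"}

    def test_equal_profiles_have_zero_perc_diff(self):
        store = _profile_store()
        cmp_ = compare_drug_profiles(store, "ALPHADRUG", "BETADRUG", include_all=True)
        by_event = {r.event: r for r in cmp_.rows}
        # RASH is 3x for drug1, NAUSEA 3x for drug2; both rows symmetric
        assert by_event["RASH"].perc_diff == pytest.approx(100.0)
        assert by_event["NAUSEA"].perc_diff == pytest.approx(-100.0)

    def test_antisymmetry_under_drug_swap(self):
        rng = random.Random(23)
        store = make_random_store(rng, 400)
        fwd = compare_drug_profiles(store, "DRUGA", "DRUGB", include_all=True)
        rev = compare_drug_profiles(store, "DRUGB", "DRUGA", include_all=True)
        fwd_map = {r.event: r.perc_diff for r in fwd.rows}
        rev_map = {r.event: r.perc_diff for r in rev.rows}
        assert fwd_map.keys() == rev_map.keys() and fwd_map
        for ev, pd in fwd_map.items():
            if pd is None:
                assert rev_map[ev] is None
            else:
                assert rev_map[ev] == pytest.approx(-pd)

    def test_cutoffs_select_extreme_rows_only(self):
        store = _profile_store()
        selected = compare_drug_profiles(
            store, "ALPHADRUG", "BETADRUG", cutoff_lo=-75, cutoff_hi=75
        )
        assert {r.event for r in selected.rows} == {"RASH", "NAUSEA"}
        all_rows = compare_drug_profiles(
            store, "ALPHADRUG", "BETADRUG", include_all=True
        )
        assert len(all_rows.rows) > len(selected.rows)

    def test_min_de_drops_sparse_events(self):
        store = _profile_store()
        cmp_ = compare_drug_profiles(
            store, "ALPHADRUG", "BETADRUG", min_de=15, include_all=True
        )
        assert {r.event for r in cmp_.rows} == {"RASH", "NAUSEA"}

    def test_truncated_event_universe_hides_signals_and_is_flagged(self):
        store = _profile_store()
        full = compare_drug_profiles(store, "ALPHADRUG", "BETADRUG", include_all=True)
        capped = compare_drug_profiles(
            store, "ALPHADRUG", "BETADRUG", include_all=True, truncate_counts=1
        )
        assert capped.truncated and not full.truncated
        assert len(capped.rows) < len(full.rows)


class TestDdiScreen:
    def test_additive_combination_gives_zero_rate_diff(self):
        reports = []

        def emit(n, drugs, reactions):
            for _ in range(n):
                reports.append(SafetyReport(
                    f"D{len(reports):04d}", drugs=frozenset(drugs),
                    reactions=frozenset(reactions)))

        emit(2, {"DRUG1"}, {"EVENTY"})
        emit(8, {"DRUG1"}, set())
        emit(1, {"DRUG2"}, {"EVENTY"})
        emit(9, {"DRUG2"}, set())
        emit(3, {"DRUG1", "DRUG2"}, {"EVENTY"})   # 0.3 == 0.2 + 0.1 exactly
        emit(7, {"DRUG1", "DRUG2"}, set())
        store = ReportStore(reports)
        screen = ddi_screen(store, "DRUG1", "DRUG2", include_all=True)
        (row,) = screen.rows
        assert row.rate_d1 == pytest.approx(0.2)
        assert row.rate_d2 == pytest.approx(0.1)
        assert row.rate_combo == pytest.approx(0.3)
        assert row.rate_diff == pytest.approx(0.0)

    def test_planted_synergy_is_most_negative_and_largest(self):
        config = SyntheticConfig(
            n_reports=40_000,
            drug_vocab=(("DRUG1", 0.15), ("DRUG2", 0.15)),
            event_vocab=(("TORSADE", 0.05), ("EVENTA", 0.01), ("EVENTB", 0.01)),
            interactions=(PlantedInteraction("DRUG1", "DRUG2", "TORSADE", 3.0),),
            seed=202,
        )
        screen = ddi_screen(generate(config), "DRUG1", "DRUG2", include_all=True)
        diffs = {r.event: r.rate_diff for r in screen.rows}
        assert diffs["TORSADE"] < 0, "combination exceeds additive expectation"
        assert min(diffs, key=diffs.get) == "TORSADE"
        assert screen.rows[0].event == "TORSADE"  # sorted by |rate_diff|

    def test_never_coreported_pair_is_flagged_with_undefined_rows(self):
        reports = [
            SafetyReport("1", drugs={"DRUG1"}, reactions={"RASH"}),
            SafetyReport("2", drugs={"DRUG2"}, reactions={"RASH"}),
        ]
        screen = ddi_screen(ReportStore(reports), "DRUG1", "DRUG2")
        assert screen.no_combination_reports
        assert screen.rows and all(r.rate_combo is None for r in screen.rows)
        assert all(r.rate_diff is None for r in screen.rows)

    def test_identical_drugs_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            ddi_screen(ReportStore(), "A", "a")


class TestBackgroundCorrection:
    def test_whole_store_mask_is_identity(self, simpson_store):
        plain = analyze_pair(simpson_store, "DRUGZ", "EVENTQ")
        masked = analyze_pair(
            simpson_store, "DRUGZ", "EVENTQ",
            Query(indication_none=frozenset({"NOSUCHIND"})),
        )
        assert plain == masked

    def test_empty_mask_undefined_and_warned(self, simpson_store, caplog):
        with caplog.at_level("WARNING", logger="pvsignal"):
            res = background_corrected(
                simpson_store, analyze_pair, "NOSUCHIND", "DRUGZ", "EVENTQ"
            )
        assert "matches no report" in caplog.text
        assert res.rrr is None

    def test_stratification_removes_confounding(self, simpson_store):
        global_rrr = analyze_pair(simpson_store, "DRUGZ", "EVENTQ").rrr
        assert global_rrr > 2
        for indication in ("CANCER", "HEADACHE"):
            within = background_corrected(
                simpson_store, analyze_pair, indication, "DRUGZ", "EVENTQ"
            )
            assert 0.8 <= within.rrr <= 1.2


class TestConfounderScreen:
    def test_fraction_of_de_subpopulation(self):
        reports = []
        for i in range(10):
            drugs = {"INDEXDRUG"} | ({"COMEDC"} if i < 7 else set())
            reports.append(SafetyReport(
                f"C{i}", drugs=frozenset(drugs), reactions=frozenset({"APLASIA"}),
                indications=frozenset({"LEUKEMIA"})))
        store = ReportStore(reports)
        screen = confounder_screen(store, "INDEXDRUG", "APLASIA")
        assert screen.n_de == 10
        assert screen.co_drugs[0] == ("COMEDC", 7, 0.7)
        # the index drug itself is excluded from the co-drug list
        assert all(t != "INDEXDRUG" for t, _, _ in screen.co_drugs)
        assert screen.co_indications[0] == ("LEUKEMIA", 10, 1.0)

    def test_top_k_larger_than_vocabulary_returns_everything(self):
        store = ReportStore([
            SafetyReport("1", drugs={"A", "B"}, reactions={"Y"}),
        ])
        screen = confounder_screen(store, "A", "Y", top_k=50)
        assert [t for t, _, _ in screen.co_drugs] == ["B"]

    def test_empty_de_subpopulation_flagged(self):
        screen = confounder_screen(ReportStore(), "A", "Y")
        assert screen.empty and screen.co_drugs == () and screen.co_indications == ()

    def test_planted_confounding_indication_tops_the_list(self):
        config = SyntheticConfig(
            n_reports=30_000,
            drug_vocab=(("SUSPECT", 0.01),),
            event_vocab=(("MARROWDAMAGE", 0.005),),
            indication_vocab=(("LEUKEMIA", 0.02), ("COLD", 0.02)),
            confounders=(PlantedConfounder("LEUKEMIA", "SUSPECT", "MARROWDAMAGE",
                                           drug_multiplier=20.0,
                                           event_multiplier=20.0),),
            seed=303,
        )
        screen = confounder_screen(generate(config), "SUSPECT", "MARROWDAMAGE")
        assert screen.n_de > 0
        assert screen.co_indications[0][0] == "LEUKEMIA"

    def test_top_k_must_be_positive(self):
        with pytest.raises(ValueError, match="top_k"):
            confounder_screen(ReportStore(), "A", "Y", top_k=0)
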