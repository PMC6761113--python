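import datetime as dt
import random

import pytest

from implantwatch.events import (
    Event,
    RegistryRecord,
    collapse_text_events,
    compare_registry,
    count_pain_mentions,
    merge_events,
    mentions_to_events,
)

D = dt.date


def ev(pid, kind, date, source="text", prov=("n",)):
    return Event(pid, kind, date, source, tuple(prov))


class FakeCand:
    def __init__(self, relation_type, note_id, pid, subclass=None, anatomy="anat:hip"):
        self.relation_type = relation_type
        self.note_id = note_id
        self.patient_id = pid

        class E:
            pass

        self.entity_a = E()
        self.entity_a.attributes = {"subclass": subclass} if subclass else {}
        self.entity_b = E()
        self.entity_b.canonical_id = anatomy


class TestMentionsToEvents:
    def test_positive_revision_mention_dated_at_note_creation(self):
        cand = FakeCand("implant_complication", "n7", "p1", subclass="revision")
        notes = {"n7": dt.datetime(2011, 2, 3, 10, 0)}
        (event,) = mentions_to_events(["positive"], [cand], notes)
        assert event.kind == "revision" and event.date == D(2011, 2, 3)
        assert event.source == "text" and event.provenance == ("n7",)

    def test_no_positive_predictions_gives_no_events(self):
        cand = FakeCand("implant_complication", "n7", "p1", subclass="revision")
        assert mentions_to_events(["negative"], [cand], {"n7": D(2011, 2, 3)}) == []

    def test_two_pain_mentions_in_one_note_give_two_events(self):
        cands = [FakeCand("pain_anatomy", "n1", "p1") for _ in range(2)]
        events = mentions_to_events(["positive", "positive"], cands, {"n1": D(2010, 1, 1)})
        assert len(events) == 2
        assert all(e.kind == "pain_mention" for e in events)

    def test_non_hip_anatomy_pain_not_an_event(self):
        cand = FakeCand("pain_anatomy", "n1", "p1", anatomy="anat:knee")
        assert mentions_to_events(["positive"], [cand], {"n1": D(2010, 1, 1)}) == []


class TestMergeEvents:
    def test_printed_strata_fixture_yields_519_unique_events(self):
        # 78 coded revision events, 504 text revision events, 63 patients
        # with a within-window coded/text pair -> 78 + 504 - 63 = 519
        coded, text = [], []
        for i in range(63):
            coded.append(ev(f"m{i}", "revision", D(2010, 3, 1), "coded", (f"c{i}",)))
            text.append(ev(f"m{i}", "revision", D(2010, 3, 20), "text", (f"t{i}",)))
        for i in range(15):
            coded.append(ev(f"c{i}", "revision", D(2011, 1, 1), "coded", (f"cc{i}",)))
        for i in range(441):
            text.append(ev(f"t{i}", "revision", D(2012, 5, 5), "text", (f"tt{i}",)))
        merged = merge_events(coded, text, window_days=60)
        assert len(merged) == 519
        n_merged = sum(1 for e in merged if e.source == "merged")
        assert n_merged == 63
        coded_covered = n_merged / len(coded)
        assert round(100 * coded_covered) == 81

    def test_merged_event_takes_earlier_timestamp(self):
        coded = [ev("p", "revision", D(2010, 5, 1), "coded", ("c",))]
        text = [ev("p", "revision", D(2010, 4, 20), "text", ("t",))]
        (merged,) = merge_events(coded, text, window_days=60)
        assert merged.source == "merged"
        assert merged.date == D(2010, 4, 20)
        assert set(merged.provenance) == {"c", "t"}

    def test_disjoint_patients_pass_through(self):
        coded = [ev("a", "revision", D(2010, 1, 1), "coded")]
        text = [ev("b", "revision", D(2010, 1, 1), "text")]
        merged = merge_events(coded, text)
        assert len(merged) == 2
        assert {e.source for e in merged} == {"coded", "text"}

    def test_outside_window_not_merged(self):
        coded = [ev("p", "revision", D(2010, 1, 1), "coded")]
        text = [ev("p", "revision", D(2010, 6, 1), "text")]
        assert len(merge_events(coded, text, window_days=60)) == 2

    def test_size_identity_and_idempotence_random_fixture(self):
        rng = random.Random(9)
        coded, text = [], []
        for i in range(40):
            pid = f"p{rng.randrange(12)}"
            coded.append(ev(pid, "revision", D(2010, 1, 1) + dt.timedelta(days=rng.randrange(900)), "coded", (f"c{i}",)))
        for i in range(90):
            pid = f"p{rng.randrange(12)}"
            text.append(ev(pid, "revision", D(2010, 1, 1) + dt.timedelta(days=rng.randrange(900)), "text", (f"t{i}",)))
        merged = merge_events(coded, text, window_days=60)
        n_pairs = sum(1 for e in merged if e.source == "merged")
        assert len(merged) == len(coded) + len(text) - n_pairs
        # idempotent: re-merging the output against nothing changes nothing
        assert merge_events(merged, [], window_days=60) == sorted(
            merged, key=lambda e: (e.patient_id, e.date, e.kind, e.source)
        )

    def test_greedy_chronological_pairing_is_deterministic(self):
        coded = [
            ev("p", "revision", D(2010, 1, 1), "coded", ("c1",)),
            ev("p", "revision", D(2010, 2, 15), "coded", ("c2",)),
        ]
        text = [
            ev("p", "revision", D(2010, 1, 10), "text", ("t1",)),
            ev("p", "revision", D(2010, 2, 20), "text", ("t2",)),
        ]
        merged = merge_events(coded, text, window_days=60)
        pairs = {e.provenance for e in merged if e.source == "merged"}
        assert pairs == {("c1", "t1"), ("c2", "t2")}


class TestCollapseTextEvents:
    def test_same_subclass_within_window_collapses(self):
        events = [
            ev("p", "infection", D(2010, 1, 1), "text", ("n1",)),
            ev("p", "infection", D(2010, 1, 20), "text", ("n2",)),
            ev("p", "infection", D(2010, 6, 1), "text", ("n3",)),
        ]
        out = collapse_text_events(events, window_days=60)
        assert len(out) == 2
        assert out[0].date == D(2010, 1, 1) and set(out[0].provenance) == {"n1", "n2"}

    def test_pain_mentions_never_collapse(self):
        events = [
            ev("p", "pain_mention", D(2010, 1, 1), "text"),
            ev("p", "pain_mention", D(2010, 1, 2), "text"),
        ]
        assert len(collapse_text_events(events)) == 2


class TestCountPainMentions:
    def pain(self, days):
        index = D(2008, 1, 1)
        return [
            ev("p", "pain_mention", index + dt.timedelta(days=d), "text") for d in days
        ], index

    def test_no_events_count_zero(self):
        events, index = self.pain([])
        assert count_pain_mentions(events, index, (0, 365)) == 0

    def test_post_year_window_excludes_day_400(self):
        events, index = self.pain([10, 100, 400])
        assert count_pain_mentions(events, index, (0, 365)) == 2

    def test_prior_year_window_counts_negative_days(self):
        events, index = self.pain([-30])
        assert count_pain_mentions(events, index, (-365, 0)) == 1

    def test_additive_over_disjoint_windows(self):
        events, index = self.pain([-200, -30, 5, 100, 364, 365, 700])
        total = count_pain_mentions(events, index, (-365, 730))
        parts = sum(
            count_pain_mentions(events, index, w)
            for w in [(-365, 0), (0, 365), (365, 730)]
        )
        assert parts == total == 7

    def test_non_pain_events_ignored(self):
        events = [ev("p", "revision", D(2008, 2, 1), "coded")]
        assert count_pain_mentions(events, D(2008, 1, 1), (0, 365)) == 0


class TestCompareRegistry:
    def reg(self, pid, comp, man, model, date=D(2005, 1, 1)):
        return RegistryRecord(pid, date, comp, man, model)

    def test_identical_entries_agree(self):
        out = [self.reg("p1", "acetabular", "Depuy", "Pinnacle")]
        registry = [self.reg("p1", "acetabular", "Depuy", "Pinnacle")]
        cmp = compare_registry(out, registry)
        assert cmp.statuses[0][3] == "agreement"

    def test_zimmer_aliases_canonicalize_before_comparison(self):
        out = [self.reg("p1", "acetabular", "Zimmer", "Trilogy")]
        registry = [self.reg("p1", "acetabular", "Zimmer Biomet", "Trilogy")]
        assert compare_registry(out, registry).statuses[0][3] == "agreement"

    def test_different_models_conflict(self):
        out = [self.reg("p1", "acetabular", "Zimmer Biomet", "Trilogy")]
        registry = [self.reg("p1", "acetabular", "Depuy", "Duraloc")]
        assert compare_registry(out, registry).statuses[0][3] == "conflict"

    def test_registry_only_row_is_missing_in_system(self):
        registry = [self.reg("p1", "femoral", "Depuy", "AML")]
        cmp = compare_registry([], registry)
        assert cmp.statuses[0][3] == "missing_in_system"

    def test_proportions_sum_to_one_and_swap_symmetry(self):
        out = [
            self.reg("p1", "acetabular", "Depuy", "Pinnacle"),
            self.reg("p1", "femoral", "Depuy", "AML"),
            self.reg("p2", "acetabular", "Zimmer", "Trilogy"),
        ]
        registry = [
            self.reg("p1", "acetabular", "Depuy", "Pinnacle"),
            self.reg("p1", "femoral", "Depuy", "Corail"),
            self.reg("p3", "femoral", "Depuy", "Summit"),
        ]
        cmp = compare_registry(out, registry)
        assert sum(cmp.proportions.values()) == pytest.approx(1.0)
        swapped = compare_registry(registry, out)
        assert swapped.proportions["agreement"] == cmp.proportions["agreement"]
        assert swapped.proportions["conflict"] == cmp.proportions["conflict"]
        assert swapped.proportions["missing_in_system"] == cmp.proportions["missing_in_registry"]
        assert swapped.proportions["missing_in_registry"] == cmp.proportions["missing_in_system"]
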