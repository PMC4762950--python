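"""Donor-tract finding, event classification against planted truth and an
exhaustive minimum-event-count oracle, and spectrum summaries."""

from fractions import Fraction

import numpy as np
import pytest

from igdiv import calling, gcv, synth

from oracles import min_event_count, window_tracts


def _sub(seq_id, subclone, pos, ref, alt):
    return calling.RawCall(seq_id, subclone, pos, calling.SUBSTITUTION, ref, alt)


def _calls_from(locus, mutseq, seq_id="s1", subclone="scA"):
    return [
        _sub(seq_id, subclone, i, r, q)
        for i, (r, q) in enumerate(zip(locus.sequence, mutseq))
        if r != q
    ]


@pytest.fixture(scope="module")
def small():
    locus = synth.make_locus(120, 0.5, seed=40)
    donors = synth.make_donor_set(locus, 3, 0.08, seed=41)
    return locus, donors


class TestFindDonorTracts:
    def test_unmutated_sequence_yields_no_mutation_bearing_candidate(self, small):
        locus, donors = small
        tracts = gcv.find_donor_tracts(locus.sequence, locus, donors)
        # candidates exist wherever locus==donor runs touch a marker boundary,
        # but none may claim a position where the sequence is actually mutated
        for t in tracts:
            for p in t.markers:
                assert locus.sequence[p] == dict(donors.donors)[t.donor_id][p]

    def test_tract_spanning_two_markers_with_support_two(self, small):
        locus, donors = small
        name, dseq = donors.donors[0]
        markers = [i for i, (a, b) in enumerate(zip(locus.sequence, dseq)) if a != b]
        assert len(markers) >= 2
        m1, m2 = markers[0], markers[1]
        mutseq = "".join(
            dseq[i] if m1 <= i <= m2 else locus.sequence[i]
            for i in range(len(locus.sequence))
        )
        tracts = [t for t in gcv.find_donor_tracts(mutseq, locus, donors)
                  if t.donor_id == name and m1 in t.markers]
        assert len(tracts) == 1
        assert set(tracts[0].markers) >= {m1, m2}

    def test_matches_sliding_window_oracle(self, small):
        locus, donors = small
        rng = np.random.default_rng(42)
        for _ in range(10):
            mutseq = list(locus.sequence)
            for p in rng.integers(0, len(mutseq), size=4):
                mutseq[p] = "ACGT"[rng.integers(4)]
            mutseq = "".join(mutseq)
            got = gcv.find_donor_tracts(mutseq, locus, donors)
            for di, (name, dseq) in enumerate(donors.donors):
                expected = window_tracts(mutseq, locus.sequence, dseq)
                mine = sorted((t.start, t.end, t.markers) for t in got if t.donor_index == di)
                assert mine == sorted(expected)

    def test_empty_donor_set_rejected(self, small):
        locus, _ = small
        with pytest.raises(ValueError):
            synth.DonorSet(donors=())


class TestClassifySequence:
    def test_unexplained_substitution_is_point_mutation(self, small):
        locus, donors = small
        # choose an alt no donor carries at position 0
        taken = {dseq[0] for _, dseq in donors.donors} | {locus.sequence[0]}
        free = [b for b in "ACGT" if b not in taken]
        if not free:
            pytest.skip("all alleles taken at position 0 for this seed")
        calls = [_sub("s1", "scA", 0, locus.sequence[0], free[0])]
        events = gcv.classify_sequence(calls, locus, donors)
        assert [e.category for e in events] == [gcv.POINT]

    def test_lone_donor_matching_substitution_is_ambiguous(self, small):
        locus, donors = small
        name, dseq = donors.donors[0]
        p = next(i for i, (a, b) in enumerate(zip(locus.sequence, dseq)) if a != b)
        calls = [_sub("s1", "scA", p, locus.sequence[p], dseq[p])]
        events = gcv.classify_sequence(calls, locus, donors)
        assert [e.category for e in events] == [gcv.AMBIGUOUS]
        assert name in events[0].donor_ids

    def test_two_jointly_explained_substitutions_form_one_event(self, small):
        locus, donors = small
        name, dseq = donors.donors[0]
        markers = [i for i, (a, b) in enumerate(zip(locus.sequence, dseq)) if a != b]
        m1, m2 = markers[0], markers[1]
        mutseq = "".join(
            dseq[i] if m1 <= i <= m2 else locus.sequence[i]
            for i in range(len(locus.sequence))
        )
        events = gcv.classify_sequence(_calls_from(locus, mutseq), locus, donors)
        gcv_events = [e for e in events if e.category == gcv.GCV]
        assert len(gcv_events) == 1
        assert {p for p, _, _ in gcv_events[0].members} == {m1, m2}

    def test_partition_every_call_in_exactly_one_event(self, locus300, donors25):
        recs, _ = synth.simulate_clone_set(
            locus300, donors25, 2, 10, 2e-3, 0.6, (30, 60), 0.0, seed=43)
        cs = calling.call_clone_set(recs, locus300)
        per_seq = {}
        for c in cs.raw_calls:
            per_seq.setdefault(c.seq_id, []).append(c)
        for seq_id, calls in per_seq.items():
            events = gcv.classify_sequence(calls, locus300, donors25)
            member_positions = [p for e in events for p, _, _ in e.members]
            assert sorted(member_positions) == sorted(c.position for c in calls)

    def test_gcv_tract_maximality(self, locus300, donors25):
        recs, _ = synth.simulate_clone_set(
            locus300, donors25, 1, 20, 0.0, 1.0, (30, 60), 0.0, seed=44)
        cs = calling.call_clone_set(recs, locus300)
        per_seq = {}
        for c in cs.raw_calls:
            per_seq.setdefault(c.seq_id, []).append(c)
        by_id = {r.seq_id: r for r in recs}
        donor_seqs = dict(donors25.donors)
        checked = 0
        for seq_id, calls in per_seq.items():
            mutseq = by_id[seq_id].sequence
            for e in gcv.classify_sequence(calls, locus300, donors25):
                if e.category != gcv.GCV:
                    continue
                for d in e.donor_ids:
                    dseq = donor_seqs[d]
                    assert mutseq[e.start:e.end] == dseq[e.start:e.end]
                    if e.start > 0:
                        assert mutseq[e.start - 1] != dseq[e.start - 1]
                    if e.end < len(locus300):
                        assert mutseq[e.end] != dseq[e.end]
                    checked += 1
        assert checked > 0

    def test_event_count_equals_exhaustive_minimum(self):
        """Greedy tract assignment reaches the exhaustive minimum event count
        on random small instances (<= 5 donors, <= 300 bp)."""
        locus = synth.make_locus(300, 0.5, seed=45)
        donors = synth.make_donor_set(locus, 5, 0.08, seed=45)
        for rep in range(30):
            recs, _ = synth.simulate_clone_set(
                locus, donors, 1, 1, 3e-3, 1.0, (20, 50), 0.0,
                seed=4500 + rep)
            calls = _calls_from(locus, recs[0].sequence)
            events = gcv.classify_sequence(calls, locus, donors)
            positions = {c.position for c in calls}
            cands = [
                frozenset(t.markers)
                for t in gcv.find_donor_tracts(recs[0].sequence, locus, donors)
            ]
            assert len(events) == min_event_count(positions, cands)


class TestClassifyEvents:
    def test_duplicated_gcv_counted_once_per_subclone(self, locus300, donors25):
        recs, truth = synth.simulate_clone_set(
            locus300, donors25, 2, 10, 0.0, 1.0, (30, 60), 1.0, seed=46)
        cs = calling.call_clone_set(recs, locus300)
        events = gcv.classify_events(cs, donors25)
        for sub in {r.subclone for r in recs}:
            planted = {
                (e.start, e.end, e.donor_id)
                for e in truth.events if e.subclone == sub and e.kind == "gcv_tract"
            }
            counted = [e for e in events if e.subclone == sub and e.category == gcv.GCV]
            assert len(counted) == len(planted)
            assert all(e.multiplicity == 10 for e in counted)

    def test_planted_category_recovery(self, locus300, donors25):
        recs, truth = synth.simulate_clone_set(
            locus300, donors25, 2, 20, 1e-3, 0.8, (30, 60), 0.0, seed=47)
        cs = calling.call_clone_set(recs, locus300)
        per_seq = {}
        for c in cs.raw_calls:
            per_seq.setdefault(c.seq_id, []).append(c)
        recovered = missed = mislabeled = 0
        for r in recs:
            events = gcv.classify_sequence(per_seq.get(r.seq_id, []), locus300, donors25)
            tract_members = [
                {p for p, _, _ in e.members} for e in events if e.category == gcv.GCV
            ]
            for te in truth.events_for(r.seq_id):
                if te.kind == "gcv_tract":
                    if any(set(te.positions) <= m for m in tract_members):
                        recovered += 1
                    else:
                        missed += 1
                elif te.kind == "point":
                    if any(te.start in m for m in tract_members):
                        mislabeled += 1
        assert recovered / max(recovered + missed, 1) >= 0.95
        assert mislabeled == 0


class TestSummarizeSpectrum:
    def test_empty_events(self):
        s = gcv.summarize_spectrum([])
        assert s.total == 0 and s.proportions == {}

    def test_proportions_are_exact_rationals(self):
        events = [
            gcv.MutationEvent("scA", gcv.POINT, i, i + 1, ((i, "A", "G"),))
            for i in range(3)
        ] + [
            gcv.MutationEvent("scA", gcv.GCV, 10, 40, ((12, "A", "C"), (30, "T", "G")),
                              donor_ids=("pseudoV01",), support=2)
        ]
        s = gcv.summarize_spectrum(events)
        assert s.proportions[gcv.POINT] == Fraction(3, 4)
        assert s.proportions[gcv.GCV] == Fraction(1, 4)
        assert s.donor_usage == {"pseudoV01": 1}
        assert s.tract_lengths == [30]
        assert sum(s.proportions.values()) == 1
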