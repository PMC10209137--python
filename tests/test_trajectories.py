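"""Trajectory construction rules: dose filter, 30-day merge, outcomes, flows."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adtraj import (PrescriptionRecord, UnknownDrugError,
                    assemble_trajectories, derive_outcomes, filter_doses,
                    switch_flow_table)


def rec(pid, drug, dose, start, end):
    return PrescriptionRecord(pid, drug, dose, start, end)


class TestFilterDoses:
    # citalopram: min 20, max 40 in the packaged table
    def test_half_minimum_boundary_kept(self, dose_table):
        kept = filter_doses([rec("p", "citalopram", 10.0, 0, 10)], dose_table)
        assert len(kept) == 1

    def test_below_half_minimum_dropped(self, dose_table):
        assert filter_doses([rec("p", "citalopram", 9.9, 0, 10)],
                            dose_table) == []

    def test_five_times_maximum_boundary_kept(self, dose_table):
        kept = filter_doses([rec("p", "citalopram", 200.0, 0, 10)], dose_table)
        assert len(kept) == 1

    def test_above_five_times_maximum_dropped(self, dose_table):
        assert filter_doses([rec("p", "citalopram", 200.1, 0, 10)],
                            dose_table) == []

    def test_empty_input_is_identity(self, dose_table):
        assert filter_doses([], dose_table) == []

    def test_unknown_drug_listed_in_error(self, dose_table):
        with pytest.raises(UnknownDrugError) as exc:
            filter_doses([rec("p", "unobtainium", 10, 0, 1),
                          rec("p", "citalopram", 20, 0, 1)], dose_table)
        assert "unobtainium" in str(exc.value)

    def test_survivors_unchanged_and_in_order(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 5),
                   rec("p", "citalopram", 5, 6, 9),
                   rec("p", "sertraline", 100, 10, 20)]
        kept = filter_doses(records, dose_table)
        assert kept == [records[0], records[2]]


class TestAssemble:
    def test_gap_of_30_days_merges(self, dose_table):
        trajs = assemble_trajectories(
            [rec("p", "citalopram", 20, 0, 10),
             rec("p", "citalopram", 20, 40, 60)], dose_table)   # gap 30
        assert len(trajs) == 1
        assert (trajs[0].start, trajs[0].end) == (0, 60)

    def test_gap_of_31_days_splits(self, dose_table):
        trajs = assemble_trajectories(
            [rec("p", "citalopram", 20, 0, 10),
             rec("p", "citalopram", 20, 41, 60)], dose_table)   # gap 31
        assert len(trajs) == 1            # only the first is the unit
        assert (trajs[0].start, trajs[0].end) == (0, 10)

    def test_different_drugs_same_class_merge(self, dose_table):
        trajs = assemble_trajectories(
            [rec("p", "citalopram", 20, 0, 10),
             rec("p", "sertraline", 100, 15, 30)], dose_table)
        assert len(trajs) == 1
        assert trajs[0].ad_class == "SSRI"
        assert trajs[0].end == 30

    def test_simultaneous_start_tie_breaks_by_class_name(self, dose_table):
        trajs = assemble_trajectories(
            [rec("p", "venlafaxine", 150, 0, 10),    # nSSRI
             rec("p", "citalopram", 20, 0, 10)],     # SSRI
            dose_table)
        assert trajs[0].ad_class == "SSRI"           # 'SSRI' < 'nSSRI'

    def test_comedication_flag_requires_overlap(self, dose_table):
        trajs = assemble_trajectories(
            [rec("p", "citalopram", 20, 0, 20),
             rec("p", "diazepam", 10, 5, 15),        # overlaps
             rec("p", "haloperidol", 5, 30, 40)],    # after the trajectory
            dose_table)
        t = trajs[0]
        assert t.co_medication["benzodiazepine"]
        assert not t.co_medication["antipsychotics"]

    def test_merge_is_order_invariant(self, dose_table):
        base = [rec("p", "citalopram", 20, 0, 10),
                rec("p", "citalopram", 30, 35, 50),
                rec("p", "sertraline", 100, 55, 80),
                rec("p", "diazepam", 10, 2, 8),
                rec("q", "mirtazapine", 30, 5, 40)]
        reference = assemble_trajectories(base, dose_table)
        rnd = random.Random(99)
        for _ in range(10):
            shuffled = base[:]
            rnd.shuffle(shuffled)
            assert assemble_trajectories(shuffled, dose_table) == reference

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(scripts=st.lists(
        st.tuples(st.sampled_from(["citalopram", "sertraline", "mirtazapine"]),
                  st.integers(0, 200), st.integers(0, 90)),
        min_size=1, max_size=8))
    def test_trajectory_interval_covers_merged_records(self, scripts, dose_table):
        records = [rec("p", drug, 20 if drug != "mirtazapine" else 30,
                       s, s + d) for drug, s, d in scripts]
        trajs = assemble_trajectories(records, dose_table)
        assert len(trajs) == 1
        t = trajs[0]
        starts = [r.start for r in records]
        assert t.start == min(starts)
        assert t.end >= t.start


class TestOutcomes:
    def test_sole_prescription_counts_as_continued(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 10)]
        t = assemble_trajectories(records, dose_table)[0]
        derive_outcomes(t, records, dose_table)
        assert t.continued is True

    def test_later_other_class_is_a_switch(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 10),
                   rec("p", "amitriptyline", 150, 60, 90)]
        t = assemble_trajectories(records, dose_table)[0]
        derive_outcomes(t, records, dose_table)
        assert t.continued is False
        assert t.final_class == "TriCA"

    def test_pause_within_same_class_is_not_a_switch(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 10),
                   rec("p", "citalopram", 20, 80, 120)]   # pause, same class
        t = assemble_trajectories(records, dose_table)[0]
        derive_outcomes(t, records, dose_table)
        assert t.continued is True

    def test_switch_and_return_is_continued(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 10),
                   rec("p", "amitriptyline", 150, 60, 90),
                   rec("p", "sertraline", 100, 150, 180)]
        t = assemble_trajectories(records, dose_table)[0]
        derive_outcomes(t, records, dose_table)
        assert t.ad_class == "SSRI"
        assert t.continued is True        # final type is an SSRI again

    def test_missing_patient_raises(self, dose_table):
        records = [rec("p", "citalopram", 20, 0, 10)]
        t = assemble_trajectories(records, dose_table)[0]
        with pytest.raises(ValueError):
            derive_outcomes(t, [], dose_table)


class TestSwitchFlows:
    def _cohort(self, dose_table):
        records = [
            rec("a", "citalopram", 20, 0, 10),
            rec("a", "amitriptyline", 150, 60, 90),      # SSRI -> TriCA
            rec("b", "mirtazapine", 30, 0, 40),          # continued
            rec("c", "venlafaxine", 150, 0, 10),
            rec("c", "tranylcypromine", 30, 100, 140),   # nSSRI -> MAOI
        ]
        trajs = assemble_trajectories(records, dose_table)
        for t in trajs:
            derive_outcomes(t, [r for r in records
                                if r.patient_id == t.patient_id], dose_table)
        return trajs, records

    def test_counts_and_conservation(self, dose_table):
        trajs, records = self._cohort(dose_table)
        flows = switch_flow_table(trajs, records, dose_table)
        assert flows.loc["SSRI", "TriCA"] == 1
        assert flows.loc["nSSRI", "MAOI"] == 1
        assert flows.values.sum() == sum(not t.continued for t in trajs)

    def test_all_continued_gives_zero_matrix(self, dose_table):
        records = [rec("a", "citalopram", 20, 0, 10)]
        trajs = assemble_trajectories(records, dose_table)
        derive_outcomes(trajs[0], records, dose_table)
        assert switch_flow_table(trajs, records, dose_table).values.sum() == 0
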