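"""Ground-truth construction, case sampling and EHR rendering."""

import numpy as np
import pytest

from adtraj import (CycleError, GroundTruthSpec, filter_doses,
                    make_ground_truth, render_ehr, sample_cases)
from adtraj.synthetic import (ehr_ground_truth, random_ground_truth,
                              to_case_table)

from conftest import joint_distribution


class TestMakeGroundTruth:
    def test_no_arcs_gives_parentless_unit_rows(self):
        bn = make_ground_truth(GroundTruthSpec(("A", "B", "C")))
        for v in "ABC":
            cpt = bn.cpts[v]
            assert cpt.parents == ()
            assert cpt.table.shape == (1, 2)
            assert cpt.table.sum() == pytest.approx(1.0)

    def test_effect_floor_contract(self):
        spec = GroundTruthSpec(("A", "B"), (("A", "B"),), cpt_seed=3,
                               effect_floor=0.3)
        bn = make_ground_truth(spec)
        t = bn.cpts["B"].table
        assert abs(t[1, 1] - t[0, 1]) >= 0.3

    @pytest.mark.parametrize("seed", range(5))
    def test_effect_floor_holds_for_every_parent(self, seed):
        """Each parent of each node moves some conditional probability by at
        least the floor, holding the other parents fixed."""
        bn = random_ground_truth(6, 8, seed=seed, effect_floor=0.25)
        for v in bn.nodes:
            cpt = bn.cpts[v]
            cards = [len(l) for l in cpt.parent_levels]
            for j, card in enumerate(cards):
                best = 0.0
                for cfg in range(cpt.n_configs):
                    assign = cpt.config_of(cfg)
                    base_level = assign[cpt.parents[j]]
                    for other in range(card):
                        if other == base_level:
                            continue
                        alt = dict(assign)
                        alt[cpt.parents[j]] = other
                        diff = np.abs(cpt.table[cfg]
                                      - cpt.table[cpt.config_index(alt)]).max()
                        best = max(best, diff)
                assert best >= 0.25 - 1e-12, (v, cpt.parents[j], best)

    def test_cycle_raises_naming_cycle(self):
        with pytest.raises(CycleError) as exc:
            make_ground_truth(GroundTruthSpec(
                ("A", "B"), (("A", "B"), ("B", "A"))))
        assert set(exc.value.cycle) == {"A", "B"}

    def test_deterministic_in_cpt_seed(self):
        spec = GroundTruthSpec(("A", "B", "C"), (("A", "B"), ("B", "C")),
                               cpt_seed=7)
        bn1, bn2 = make_ground_truth(spec), make_ground_truth(spec)
        for v in bn1.nodes:
            np.testing.assert_array_equal(bn1.cpts[v].table, bn2.cpts[v].table)

    def test_invalid_effect_floor_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(("A",), effect_floor=1.5)


class TestSampleCases:
    def test_degenerate_cpt_is_respected(self):
        spec = GroundTruthSpec(("A",), anchors={"A": 1.0})
        bn = make_ground_truth(spec)
        cases = sample_cases(bn, 50, seed=0)
        assert (cases["A"] == 1).all()

    def test_marginal_frequency_within_binomial_bound(self):
        """P(A=1)=0.5 at n=10,000: empirical frequency within 0.02 (4 sigma)."""
        bn = make_ground_truth(GroundTruthSpec(("A",), anchors={"A": 0.5}))
        cases = sample_cases(bn, 10_000, seed=1)
        assert abs(cases["A"].mean() - 0.5) < 0.02

    def test_conditional_frequencies_track_cpt(self):
        """Chain with P(B=1|A) = 0.9/0.1: empirical conditionals within 0.03."""
        spec = GroundTruthSpec(("A", "B"), (("A", "B"),))
        bn = make_ground_truth(spec)
        bn.cpts["B"].table[:] = [[0.9, 0.1], [0.1, 0.9]]
        cases = sample_cases(bn, 10_000, seed=2)
        for a in (0, 1):
            sub = cases[cases["A"] == a]
            assert abs(sub["B"].mean() - bn.cpts["B"].table[a, 1]) < 0.03

    def test_joint_converges_in_total_variation(self):
        """Empirical joint within TV 0.02 of the exact joint on 3 nodes at
        n = 50,000."""
        bn = make_ground_truth(GroundTruthSpec(
            ("A", "B", "C"), (("A", "B"), ("B", "C")), cpt_seed=5,
            effect_floor=0.3))
        joint = joint_distribution(bn)
        cases = sample_cases(bn, 50_000, seed=3)
        tv = 0.0
        for assign, p in joint.items():
            emp = np.mean((cases["A"] == assign[0]) & (cases["B"] == assign[1])
                          & (cases["C"] == assign[2]))
            tv += abs(emp - p)
        assert tv / 2 < 0.02

    def test_rejects_nonpositive_n(self):
        bn = make_ground_truth(GroundTruthSpec(("A",)))
        with pytest.raises(ValueError):
            sample_cases(bn, 0, seed=0)


@pytest.fixture(scope="module")
def cohort(dose_table):
    bn = ehr_ground_truth(cpt_seed=1)
    cases = sample_cases(bn, 300, seed=4)
    return cases, render_ehr(cases, seed=5, dose_table=dose_table,
                             corruption_rate=0.0, gaf_missing_rate=0.2)


class TestRenderEhr:
    def test_duration_node_controls_span(self, cohort, dose_table):
        cases, raw = cohort
        spans = {}
        for r in raw.prescriptions:
            if dose_table.category(r.drug_name) not in (
                    "benzodiazepine", "lithium", "antipsychotics", "disulfiram"):
                lo, hi = spans.get(r.patient_id, (r.start, r.end))
                # only the first trajectory: ignore later scripts (gap > 30)
                if r.start - hi <= 30:
                    spans[r.patient_id] = (min(lo, r.start), max(hi, r.end))
                else:
                    spans.setdefault(r.patient_id, (lo, hi))
        for i, flag in enumerate(cases["duration_ge_5w"]):
            lo, hi = spans[f"P{i:05d}"]
            assert (hi - lo >= 35) == bool(flag)

    def test_no_corruption_means_no_filtered_records(self, cohort, dose_table):
        _, raw = cohort
        assert len(filter_doses(raw.prescriptions, dose_table)) == len(
            raw.prescriptions)

    def test_corruption_rate_injects_implausible_doses(self, dose_table):
        bn = ehr_ground_truth(cpt_seed=1)
        cases = sample_cases(bn, 200, seed=6)
        raw = render_ehr(cases, seed=7, dose_table=dose_table,
                         corruption_rate=0.25)
        kept = filter_doses(raw.prescriptions, dose_table)
        assert len(raw.prescriptions) - len(kept) == round(0.25 * 200)

    def test_gaf_missingness_fraction_exact(self, cohort):
        _, raw = cohort
        assert int(raw.gaf["gaf"].isna().sum()) == round(0.2 * 300)

    def test_byte_identical_for_same_seed(self, dose_table, tmp_path):
        bn = ehr_ground_truth(cpt_seed=2)
        cases = sample_cases(bn, 100, seed=8)
        for sub in ("a", "b"):
            render_ehr(cases, seed=9, dose_table=dose_table,
                       corruption_rate=0.1).write(tmp_path / sub)
        for name in ("prescriptions.csv", "patients.csv", "gaf.csv",
                     "sentiment_events.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_invalid_corruption_rate(self, cohort, dose_table):
        cases, _ = cohort
        with pytest.raises(ValueError):
            render_ehr(cases, seed=0, dose_table=dose_table,
                       corruption_rate=1.5)

    def test_case_table_expansion_is_one_hot(self):
        bn = ehr_ground_truth()
        cases = sample_cases(bn, 500, seed=10)
        ct = to_case_table(cases)
        ad_cols = [c for c in ct.columns if c.startswith("ad_")]
        assert (ct[ad_cols].sum(axis=1) == 1).all()
        assert ct.shape == (500, 23)
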