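"""Parameter fitting, exact queries, logic sampling and probability deltas."""

import itertools

import numpy as np
import pytest

from adtraj import (DAG, BayesianNetwork, CPT, InsufficientAcceptanceError,
                    Query, ZeroEvidenceError, d_separated, exact_query,
                    fit_mle, logic_sampling_query, probability_delta)
from adtraj.synthetic import (GroundTruthSpec, make_ground_truth,
                              random_ground_truth, sample_cases)

from conftest import conditional_prob, joint_distribution


def toy_network():
    """Three binary nodes A -> B, (A, B) -> C with an interaction: without B,
    A has no effect on C."""
    dag = DAG("ABC", [("A", "B"), ("A", "C"), ("B", "C")])
    cpts = {
        "A": CPT("A", (), (0, 1), (), [[0.7, 0.3]]),
        "B": CPT("B", ("A",), (0, 1), ((0, 1),), [[0.6, 0.4], [0.3, 0.7]]),
        "C": CPT("C", ("A", "B"), (0, 1), ((0, 1), (0, 1)),
                 [[0.9, 0.1], [0.5, 0.5], [0.9, 0.1], [0.2, 0.8]]),
    }
    return BayesianNetwork(dag, cpts)


class TestFitMle:
    def test_parentless_relative_frequency(self):
        data = {"A": np.array([1] * 7 + [0] * 3)}
        bn = fit_mle(DAG("A"), data)
        assert bn.cpts["A"].table[0, 1] == pytest.approx(0.7)

    def test_unobserved_parent_configuration_gets_uniform_row(self):
        data = {"A": np.zeros(20, dtype=int),
                "B": np.random.default_rng(0).integers(0, 2, 20)}
        bn = fit_mle(DAG("AB", [("A", "B")]), data,
                     levels={"A": (0, 1), "B": (0, 1)})
        np.testing.assert_allclose(bn.cpts["B"].table[1], [0.5, 0.5])
        assert bn.flagged_rows["B"] == [1]

    def test_parameter_recovery_at_scale(self):
        """Refit on 50,000 samples recovers every CPT entry within 0.02.

        The ground truth is layered with balanced roots so that each parent
        configuration carries thousands of rows and the tolerance is a
        multi-sigma bound rather than a coin flip."""
        from conftest import layered_ground_truth

        truth = layered_ground_truth(seed=3)
        data = sample_cases(truth, 50_000, seed=4)
        refit = fit_mle(truth.dag, data)
        for v in truth.nodes:
            np.testing.assert_allclose(refit.cpts[v].table,
                                       truth.cpts[v].table, atol=0.02)


class TestExactQuery:
    def test_parentless_no_evidence_reads_cpt(self):
        bn = toy_network()
        assert exact_query(bn, Query("A", 1)) == pytest.approx(0.3)

    def test_dependence_shifts_child_probability(self):
        """Knowing the parent occurred moves P(B) from its prior 0.4-style
        row to the conditional 0.7 row, as the toy CPT encodes."""
        bn = toy_network()
        assert exact_query(bn, Query("B", 1, {"A": 1})) == pytest.approx(0.7)
        assert exact_query(bn, Query("B", 1, {"A": 0})) == pytest.approx(0.4)

    def test_interaction_captured(self):
        """In the absence of B the effect of A on C disappears."""
        bn = toy_network()
        assert (exact_query(bn, Query("C", 1, {"A": 1, "B": 0}))
                == pytest.approx(exact_query(bn, Query("C", 1, {"A": 0, "B": 0}))))
        assert (exact_query(bn, Query("C", 1, {"A": 1, "B": 1}))
                > exact_query(bn, Query("C", 1, {"A": 0, "B": 1})))

    def test_full_evidence_is_deterministic(self):
        bn = toy_network()
        assert exact_query(bn, Query("C", 1, {"A": 1, "B": 1})) == (
            pytest.approx(0.8))
        assert exact_query(bn, Query("A", 1, {"B": 1, "C": 1})) == (
            pytest.approx(conditional_prob(joint_distribution(bn), bn.nodes,
                                           "A", 1, {"B": 1, "C": 1})))

    def test_marginals_sum_to_one(self):
        bn = toy_network()
        for v in bn.nodes:
            total = sum(exact_query(bn, Query(v, k)) for k in (0, 1))
            assert total == pytest.approx(1.0)

    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            bn = random_ground_truth(5, 6, seed=seed, effect_floor=0.2)
            joint = joint_distribution(bn)
            for _ in range(5):
                nodes = list(bn.nodes)
                rng.shuffle(nodes)
                target, evs = nodes[0], nodes[1:1 + int(rng.integers(0, 3))]
                evidence = {e: int(rng.integers(0, 2)) for e in evs}
                expected = conditional_prob(joint, bn.nodes, target, 1, evidence)
                got = exact_query(bn, Query(target, 1, evidence))
                assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_evidence_raises(self):
        spec = GroundTruthSpec(("A", "B"), anchors={"A": 1.0, "B": 0.5})
        bn = make_ground_truth(spec)
        with pytest.raises(ZeroEvidenceError):
            exact_query(bn, Query("B", 1, {"A": 0}))

    def test_dseparated_evidence_never_changes_result(self):
        for seed in range(3):
            bn = random_ground_truth(5, 5, seed=seed + 50, effect_floor=0.25)
            nodes = bn.nodes
            for x, y in itertools.combinations(nodes, 2):
                if d_separated(bn.dag, x, y, set()):
                    base = exact_query(bn, Query(x, 1))
                    cond = exact_query(bn, Query(x, 1, {y: 1}))
                    assert cond == pytest.approx(base, abs=1e-12)


class TestLogicSampling:
    def test_matches_exact_within_three_standard_errors(self):
        bn = toy_network()
        q = Query("C", 1, {"A": 1}, n_samples=50_000, seed=7)
        est = logic_sampling_query(bn, q)
        exact = exact_query(bn, q)
        assert abs(est.probability - exact) <= 3 * max(est.standard_error, 1e-4)

    def test_deterministic_ancestors_match_exactly(self):
        spec = GroundTruthSpec(("A", "B"), (("A", "B"),), anchors={"A": 1.0})
        bn = make_ground_truth(spec)
        p_b = bn.cpts["B"].table[1, 1]
        est = logic_sampling_query(bn, Query("B", 1, {"A": 1},
                                             n_samples=20_000, seed=8))
        assert est.probability == pytest.approx(p_b, abs=0.02)
        assert est.n_accepted == 20_000

    def test_error_shrinks_with_more_samples(self):
        """Mean absolute error halves-ish when n_samples quadruples."""
        bn = toy_network()
        exact = exact_query(bn, Query("C", 1, {"B": 1}))
        errs = {}
        for n in (500, 8000):
            errors = [abs(logic_sampling_query(
                bn, Query("C", 1, {"B": 1}, n_samples=n, seed=s)).probability
                - exact) for s in range(20)]
            errs[n] = np.mean(errors)
        assert errs[8000] < errs[500]

    def test_impossible_evidence_raises_not_zero(self):
        spec = GroundTruthSpec(("A", "B"), anchors={"A": 1.0, "B": 0.5})
        bn = make_ground_truth(spec)
        with pytest.raises(InsufficientAcceptanceError):
            logic_sampling_query(bn, Query("B", 1, {"A": 0},
                                           n_samples=1000, seed=9))

    def test_rejects_bad_sample_count(self):
        with pytest.raises(ValueError):
            logic_sampling_query(toy_network(), Query("A", 1, n_samples=0))


class TestProbabilityDelta:
    def test_identical_evidence_gives_zero(self):
        bn = toy_network()
        assert probability_delta(bn, "C", 1, {"A": 1}, {"A": 1}) == 0.0

    def test_dseparated_change_gives_zero(self):
        """Changing evidence on a variable d-separated from the target given
        the shared evidence cannot move the probability."""
        dag = DAG("ABC", [("A", "B"), ("B", "C")])
        cpts = {
            "A": CPT("A", (), (0, 1), (), [[0.5, 0.5]]),
            "B": CPT("B", ("A",), (0, 1), ((0, 1),), [[0.8, 0.2], [0.3, 0.7]]),
            "C": CPT("C", ("B",), (0, 1), ((0, 1),), [[0.9, 0.1], [0.4, 0.6]]),
        }
        bn = BayesianNetwork(dag, cpts)
        delta = probability_delta(bn, "C", 1, {"B": 1, "A": 0}, {"B": 1, "A": 1})
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_sign_and_magnitude_match_enumeration(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            bn = random_ground_truth(5, 6, seed=seed + 200, effect_floor=0.25)
            joint = joint_distribution(bn)
            nodes = list(bn.nodes)
            target = nodes[-1]
            changed = nodes[0]
            shared = {nodes[2]: int(rng.integers(0, 2))}
            base = {**shared, changed: 0}
            alt = {**shared, changed: 1}
            try:
                expected = 100 * (
                    conditional_prob(joint, bn.nodes, target, 1, alt)
                    - conditional_prob(joint, bn.nodes, target, 1, base))
            except ZeroDivisionError:
                continue
            got = probability_delta(bn, target, 1, base, alt)
            assert got == pytest.approx(expected, abs=1e-9)
            if abs(expected) > 1e-9:
                assert np.sign(got) == np.sign(expected)
            else:
                assert abs(got) <= 1e-9
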