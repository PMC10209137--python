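"""Shared fixtures and independent oracles for the test suite.

The joint-distribution helpers here enumerate tiny networks exhaustively and
deliberately avoid the package's own inference code paths, so they can serve
as independent checks of variable elimination, sampling and d-separation.
"""

from __future__ import annotations

import itertools

import pytest

from adtraj import DAG, BayesianNetwork, DoseTable


@pytest.fixture(scope="session")
def dose_table() -> DoseTable:
    return DoseTable.default()


def joint_distribution(bn: BayesianNetwork) -> dict[tuple, float]:
    """Exhaustive joint P(assignment) as a dict keyed by level-index tuples
    in ``bn.nodes`` order.  Brute force: product of CPT entries."""
    cards = [len(bn.levels(v)) for v in bn.nodes]
    node_pos = {v: i for i, v in enumerate(bn.nodes)}
    joint = {}
    for assignment in itertools.product(*(range(c) for c in cards)):
        p = 1.0
        for v in bn.nodes:
            cpt = bn.cpts[v]
            cfg = 0
            for par, lv in zip(cpt.parents, cpt.parent_levels):
                cfg = cfg * len(lv) + assignment[node_pos[par]]
            p *= cpt.table[cfg, assignment[node_pos[v]]]
        joint[assignment] = p
    return joint


def conditional_prob(joint: dict[tuple, float], nodes: tuple[str, ...],
                     target: str, value, evidence: dict) -> float:
    """P(target = value | evidence) from an enumerated joint (oracle)."""
    pos = {v: i for i, v in enumerate(nodes)}
    num = den = 0.0
    for assign, p in joint.items():
        if all(assign[pos[k]] == v for k, v in evidence.items()):
            den += p
            if assign[pos[target]] == value:
                num += p
    if den == 0:
        raise ZeroDivisionError("evidence has probability zero")
    return num / den


def dependence_measure(joint: dict[tuple, float], nodes: tuple[str, ...],
                       x: str, y: str, z: tuple[str, ...]) -> float:
    """max |P(x,y|z) - P(x|z) P(y|z)| over configurations with P(z) > 0."""
    pos = {v: i for i, v in enumerate(nodes)}
    cards = {}
    for assign in joint:
        for v, i in pos.items():
            cards[v] = max(cards.get(v, 0), assign[i] + 1)
    worst = 0.0
    for zv in itertools.product(*(range(cards[c]) for c in z)):
        pz = sum(p for a, p in joint.items()
                 if all(a[pos[c]] == v for c, v in zip(z, zv)))
        if pz <= 0:
            continue
        for xv in range(cards[x]):
            for yv in range(cards[y]):
                pxy = sum(p for a, p in joint.items()
                          if a[pos[x]] == xv and a[pos[y]] == yv
                          and all(a[pos[c]] == v for c, v in zip(z, zv))) / pz
                px = sum(p for a, p in joint.items() if a[pos[x]] == xv
                         and all(a[pos[c]] == v for c, v in zip(z, zv))) / pz
                py = sum(p for a, p in joint.items() if a[pos[y]] == yv
                         and all(a[pos[c]] == v for c, v in zip(z, zv))) / pz
                worst = max(worst, abs(pxy - px * py))
    return worst


def all_dags(nodes: tuple[str, ...]):
    """Every labelled DAG on ``nodes`` by brute force over arc subsets."""
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    for mask in range(2 ** len(pairs)):
        arcs = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if any((b, a) in arcs for a, b in arcs):
            continue
        try:
            yield DAG(nodes, arcs)
        except Exception:
            continue


def layered_ground_truth(seed: int, effect_floor: float = 0.3):
    """Two-layer balanced ground truth for parameter-recovery experiments:
    roots at P=0.5 and children fed only by roots, so every parent
    configuration carries about a quarter of the sample."""
    from adtraj import GroundTruthSpec, make_ground_truth

    spec = GroundTruthSpec(
        node_names=("A", "B", "C", "D", "E", "F"),
        arcs=(("A", "D"), ("B", "D"), ("B", "E"), ("C", "E"),
              ("A", "F"), ("C", "F")),
        cpt_seed=seed,
        effect_floor=effect_floor,
        anchors={"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5, "E": 0.5, "F": 0.5},
    )
    return make_ground_truth(spec)
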