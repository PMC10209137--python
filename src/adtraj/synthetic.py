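"""Synthetic EHR cohorts with a known ground-truth Bayesian network.

The clinical data behind this kind of trajectory analysis cannot be shared,
so verification runs on cohorts whose generating mechanism is known exactly:
a ground-truth network over the analysis variables is built (with CPT effects
bounded away from zero, so its arcs are detectable), binary cases are
ancestrally sampled from it, and each case is rendered *backwards* into raw
EHR-style records — prescriptions with doses and day-indexed intervals,
demographics, DSM flags, GAF scores with missingness, per-theme sentiment
events — which the pipeline must then reconstruct.

Antidepressant class is one categorical (six-level) node in the ground truth
and becomes six mutually exclusive indicator columns in the analysis case
table, mirroring how the class enters the learned networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayesnet import CPT, BayesianNetwork
from .graphs import DAG
from .sentiment import THEMES, SentimentEvent, write_sentiment_csv
from .trajectories import (AD_CLASSES, CO_MED_CLASSES, DoseTable,
                           PrescriptionRecord, write_prescriptions_csv)
from .discretize import DX_FLAGS

CLASS_NODE = "ad_class"

#: binary ground-truth nodes shared with the analysis case table
BINARY_NODES: tuple[str, ...] = (
    "sex_female", "age_ge_48",
    *CO_MED_CLASSES,
    *DX_FLAGS,
    "gaf_ge_50", "duration_ge_5w", "continued",
    *(f"sent_{t}" for t in THEMES),
)

#: Table-1-style base rates used to anchor the default ground truth
_BASE_RATES: dict[str, float] = {
    "sex_female": 0.577, "age_ge_48": 0.50,
    "benzodiazepine": 0.643, "lithium": 0.081,
    "antipsychotics": 0.423, "disulfiram": 0.015,
    "dx_depression": 0.401, "dx_personality": 0.268,
    "dx_anxiety": 0.077, "dx_social": 0.025,
    "gaf_ge_50": 0.42, "duration_ge_5w": 0.55, "continued": 0.663,
    "sent_core_complaints": 0.45, "sent_social_functioning": 0.65,
    "sent_well_being": 0.65, "sent_experience": 0.45,
}

# cohort class mix (MAOI, SSRI, TetraCA, TriCA, nSSRI, other order), normalised
_CLASS_RATES = np.array([0.013, 0.467, 0.172, 0.177, 0.161, 0.047])
_CLASS_RATES = _CLASS_RATES / _CLASS_RATES.sum()

#: default dependency structure: co-medication drives the duration and
#: sentiment outcomes, class and depression diagnosis drive continuation,
#: and the outcome nodes are intertwined
DEFAULT_ARCS: tuple[tuple[str, str], ...] = (
    ("age_ge_48", "dx_depression"),
    ("dx_social", "dx_depression"),
    ("dx_depression", "continued"),
    (CLASS_NODE, "continued"),
    ("benzodiazepine", "sent_well_being"),
    ("antipsychotics", "sent_well_being"),
    ("benzodiazepine", "sent_social_functioning"),
    ("antipsychotics", "sent_social_functioning"),
    ("sent_well_being", "duration_ge_5w"),
    ("benzodiazepine", "duration_ge_5w"),
    ("antipsychotics", "duration_ge_5w"),
    ("duration_ge_5w", "sent_experience"),
    ("sent_well_being", "sent_core_complaints"),
    ("dx_anxiety", "sent_core_complaints"),
    ("dx_personality", "gaf_ge_50"),
)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Recipe for a ground-truth network: nodes, arcs and CPT constraints.

    ``effect_floor`` bounds from below the conditional-probability contrast
    every parent must exert (some pair of parent configurations differing only
    in that parent differs by at least this much), so that arcs are
    statistically detectable at the configured sample size.
    """

    node_names: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...] = ()
    cpt_seed: int = 0
    effect_floor: float = 0.25
    n_cases: int = 4808
    node_levels: Mapping[str, int] = field(default_factory=dict)
    anchors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_floor <= 1.0:
            raise ValueError("effect_floor must lie in [0, 1]")
        names = set(self.node_names)
        for a, b in self.arcs:
            if a not in names or b not in names:
                raise ValueError(f"arc endpoint not in node_names: {a}->{b}")


def _binary_child_probs(rng: np.random.Generator, parent_cards: Sequence[int],
                        effect_floor: float, anchor: float | None,
                        parent_margs: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """P(node = 1) per parent configuration with guaranteed per-parent
    contrast: an additive effect per parent, constructed so the
    reference-configuration contrasts are never clipped.

    Rows are kept a margin away from 0 and 1 so no variable is nearly
    constant in any stratum: near-deterministic rows would dilute marginal
    associations and make arcs undetectable, defeating the point of the
    effect floor."""
    margin = min(0.1, (1.0 - effect_floor) / 2.0)
    sizes = []
    for _ in parent_cards:
        head = effect_floor + rng.uniform(
            0.0, max(min(0.15, 1.0 - 2 * margin - effect_floor), 0.0))
        sizes.append(head)
    signs = rng.choice([-1.0, 1.0], size=len(parent_cards))

    # per-parent, per-level offsets; level 0 is the reference
    offsets = []
    for card, e, s in zip(parent_cards, sizes, signs):
        if card == 2:
            offsets.append(np.array([0.0, s * e]))
        else:
            raw = rng.uniform(0.0, 1.0, card)
            raw -= raw.min()
            raw = raw / max(raw.max(), 1e-12) * e * s
            raw -= raw[0]           # reference level offset 0
            offsets.append(raw)

    lo = margin + max((-o.min() for o in offsets), default=0.0)
    hi = 1.0 - margin - max((o.max() for o in offsets), default=0.0)
    if lo > hi:  # very large effects with several parents: centre the window
        lo = hi = 0.5
    # aim the *marginal* rate at the anchor: subtract the offset the parent
    # mix contributes in expectation (the contrast guarantee only involves
    # offset differences, so it is unaffected)
    if parent_margs is None:
        mean_offset = sum(float(o.mean()) for o in offsets)
    else:
        mean_offset = sum(float(np.dot(m, o))
                          for m, o in zip(parent_margs, offsets))
    target = (anchor - mean_offset) if anchor is not None else rng.uniform(0.35, 0.65)
    base = float(np.clip(target, lo, hi))

    q = int(np.prod(parent_cards))
    p = np.empty(q)
    for cfg in range(q):
        rest, total = cfg, base
        for card, off in zip(reversed(parent_cards), reversed(offsets)):
            total += off[rest % card]
            rest //= card
        p[cfg] = total
    return np.clip(p, margin / 2, 1.0 - margin / 2)


def make_ground_truth(spec: GroundTruthSpec) -> BayesianNetwork:
    """Materialise a ground-truth network from ``spec``.

    CPT entries are reproducible from ``cpt_seed``; for every node with
    parents, each parent's conditional-probability contrast meets
    ``effect_floor`` (a stronger guarantee than the minimum needed for
    detectability, applied uniformly).  A cyclic arc set raises
    :class:`~adtraj.graphs.CycleError` naming one cycle.
    """
    dag = DAG(spec.node_names, spec.arcs)   # raises CycleError on cycles
    rng = np.random.default_rng(spec.cpt_seed)
    cards = {v: int(spec.node_levels.get(v, 2)) for v in spec.node_names}
    cpts: dict[str, CPT] = {}
    # approximate node marginals (parents treated as independent), kept so
    # child base rates can be aimed at their anchors in the marginal
    margs: dict[str, np.ndarray] = {}
    topo = {v: i for i, v in enumerate(dag.topological_order())}
    for v in sorted(spec.node_names, key=lambda u: topo[u]):
        ps = dag.parents(v)
        r = cards[v]
        levels = tuple(range(r))
        plv = tuple(tuple(range(cards[p])) for p in ps)
        p_cards = [cards[p] for p in ps]
        anchor = spec.anchors.get(v)
        if r == 2:
            if ps:
                p1 = _binary_child_probs(rng, p_cards, spec.effect_floor,
                                         anchor, [margs[p] for p in ps])
                # config weights under parent independence (first parent most
                # significant), giving the approximate marginal
                w = np.array([1.0])
                for p in ps:
                    w = np.kron(w, margs[p])
                m1 = float(w @ p1)
                margs[v] = np.array([1.0 - m1, m1])
            else:
                p1 = np.array([anchor if anchor is not None
                               else rng.uniform(0.25, 0.75)])
                margs[v] = np.array([1.0 - p1[0], p1[0]])
            table = np.column_stack([1.0 - p1, p1])
        else:
            if ps:
                raise NotImplementedError(
                    "multi-level nodes are supported as roots only")
            probs = (np.asarray(spec.anchors.get(v, None), dtype=float)
                     if isinstance(spec.anchors.get(v), (list, tuple, np.ndarray))
                     else rng.dirichlet(np.full(r, 2.0)))
            table = probs.reshape(1, r) / probs.sum()
            margs[v] = table[0].copy()
        cpts[v] = CPT(v, ps, levels, plv, table)
    return BayesianNetwork(dag, cpts)


def ehr_ground_truth(cpt_seed: int = 0, effect_floor: float = 0.25,
                     arcs: Sequence[tuple[str, str]] = DEFAULT_ARCS,
                     n_cases: int = 4808) -> BayesianNetwork:
    """The default cohort-generating network: one six-level class node plus
    seventeen binary nodes, base rates anchored at the reference cohort's
    observed proportions."""
    spec = GroundTruthSpec(
        node_names=(CLASS_NODE, *BINARY_NODES),
        arcs=tuple(arcs),
        cpt_seed=cpt_seed,
        effect_floor=effect_floor,
        n_cases=n_cases,
        node_levels={CLASS_NODE: len(AD_CLASSES)},
        anchors={CLASS_NODE: tuple(_CLASS_RATES), **_BASE_RATES},
    )
    return make_ground_truth(spec)


def random_ground_truth(n_nodes: int, n_arcs: int, seed: int,
                        effect_floor: float = 0.25,
                        max_parents: int = 5) -> BayesianNetwork:
    """A random sparse all-binary ground truth for benchmarking recovery."""
    rng = np.random.default_rng(seed)
    names = tuple(f"V{i:02d}" for i in range(n_nodes))
    order = rng.permutation(n_nodes)
    arcs: set[tuple[str, str]] = set()
    parents_ct = {v: 0 for v in names}
    attempts = 0
    while len(arcs) < n_arcs and attempts < 50 * n_arcs:
        attempts += 1
        i, j = sorted(rng.choice(n_nodes, size=2, replace=False))
        a, b = names[order[i]], names[order[j]]
        if (a, b) in arcs or parents_ct[b] >= max_parents:
            continue
        arcs.add((a, b))
        parents_ct[b] += 1
    spec = GroundTruthSpec(names, tuple(sorted(arcs)),
                           cpt_seed=int(rng.integers(2 ** 31)),
                           effect_floor=effect_floor)
    return make_ground_truth(spec)


def random_tree_ground_truth(n_nodes: int, seed: int,
                             effect_floor: float = 0.3) -> BayesianNetwork:
    """A connected sparse ground truth: the skeleton is a uniform random
    recursive tree (n-1 arcs) and edges are oriented along a random node
    order, so colliders arise at nodes whose tree neighbours both precede
    them.

    Connectivity matters for recovery benchmarks: a falsely added edge
    touching an isolated node admits no conditioning subset, so no
    constraint-based learner can re-test it and its false-positive rate is
    exactly the test level.
    """
    rng = np.random.default_rng(seed)
    names = tuple(f"V{i:02d}" for i in range(n_nodes))
    labels = rng.permutation(n_nodes)
    tree_edges = []
    for j in range(1, n_nodes):
        i = int(rng.integers(0, j))
        tree_edges.append((int(labels[i]), int(labels[j])))
    order = {int(v): k for k, v in enumerate(rng.permutation(n_nodes))}
    arcs = tuple(sorted(
        (names[a], names[b]) if order[a] < order[b] else (names[b], names[a])
        for a, b in tree_edges))
    spec = GroundTruthSpec(names, arcs, cpt_seed=int(rng.integers(2 ** 31)),
                           effect_floor=effect_floor)
    return make_ground_truth(spec)


def _exact_joint(bn: BayesianNetwork) -> tuple[np.ndarray, list[int]]:
    """Joint probability tensor over all nodes (levels as axes), by brute
    force; only sensible for small networks."""
    cards = [len(bn.levels(v)) for v in bn.nodes]
    pos = {v: i for i, v in enumerate(bn.nodes)}
    joint = np.ones(cards)
    for v in bn.nodes:
        cpt = bn.cpts[v]
        axes = [pos[p] for p in cpt.parents] + [pos[v]]
        factor_shape = [len(l) for l in cpt.parent_levels] + [len(cpt.levels)]
        arr = cpt.table.reshape(factor_shape)
        arr = np.transpose(arr, np.argsort(axes))
        joint = joint * arr.reshape([cards[i] if i in axes else 1
                                     for i in range(len(cards))])
    return joint, cards


def _max_dependence(joint: np.ndarray, i: int, j: int, z: tuple[int, ...]) -> float:
    """max |P(x,y|z) - P(x|z)P(y|z)| over strata with positive mass."""
    axes_keep = sorted({i, j, *z})
    drop = tuple(a for a in range(joint.ndim) if a not in axes_keep)
    marg = joint.sum(axis=drop)
    pos_map = {a: k for k, a in enumerate(axes_keep)}
    ii, jj = pos_map[i], pos_map[j]
    zz = [pos_map[a] for a in z]
    worst = 0.0
    it = np.ndindex(*[marg.shape[k] for k in zz]) if zz else [()]
    for zv in it:
        idx = [slice(None)] * marg.ndim
        for k, v in zip(zz, zv):
            idx[k] = v
        block = marg[tuple(idx)]
        pz = block.sum()
        if pz <= 0:
            continue
        block = block / pz
        # axes of block: ii and jj in their relative order
        if ii > jj:
            block = block.T
        px = block.sum(axis=1, keepdims=True)
        py = block.sum(axis=0, keepdims=True)
        worst = max(worst, float(np.abs(block - px * py).max()))
    return worst


def strongly_faithful_ground_truth(n_nodes: int, n_arcs: int, seed: int,
                                   effect_floor: float = 0.3,
                                   min_dependence: float = 0.03,
                                   max_parents: int = 3,
                                   max_tries: int = 300,
                                   connected: bool = False) -> BayesianNetwork:
    """A random ground truth strongly faithful where recovery needs it:
    adjacent pairs keep conditional dependence at least ``min_dependence``
    under *every* conditioning set (so no true edge can be falsely removed),
    and spouse/unshielded-triple pairs keep it under every set that does not
    truly d-separate them (so recorded separating sets are true separators
    and v-structures orient correctly).  Distant pairs are unconstrained:
    their (weak) long-range dependence plays no role in identifiability.

    Constraint-based learners are only uniformly consistent under this kind
    of strong-faithfulness condition, so recovery benchmarks draw their
    truths from this family (candidates screened by exact joint enumeration;
    feasible for small networks only).
    """
    from itertools import combinations

    from .graphs import d_separated

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        sub = int(rng.integers(2 ** 31))
        if connected:
            bn = random_tree_ground_truth(n_nodes, sub, effect_floor)
        else:
            bn = random_ground_truth(n_nodes, n_arcs, sub, effect_floor,
                                     max_parents)
        joint, _ = _exact_joint(bn)
        pos = {v: k for k, v in enumerate(bn.nodes)}
        skel = {tuple(sorted(e)) for e in bn.dag.arcs}
        neigh: dict[str, set[str]] = {v: set() for v in bn.nodes}
        for a, b in bn.dag.arcs:
            neigh[a].add(b)
            neigh[b].add(a)
        ok = True
        for x, y in combinations(bn.nodes, 2):
            adjacent = tuple(sorted((x, y))) in skel
            if not adjacent and not (neigh[x] & neigh[y]):
                continue   # distant pair: irrelevant to identifiability
            others = [v for v in bn.nodes if v not in (x, y)]
            for k in range(len(others) + 1):
                for zs in combinations(others, k):
                    if not adjacent and d_separated(bn.dag, x, y, set(zs)):
                        continue
                    dep = _max_dependence(joint, pos[x], pos[y],
                                          tuple(pos[v] for v in zs))
                    if dep < min_dependence:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return bn
    raise RuntimeError("no strongly faithful ground truth found; relax "
                       "min_dependence or raise max_tries")


def sample_cases(bn: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sample of ``n`` complete cases (level indices per node)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = bn.sample(n, rng)
    return pd.DataFrame({v: draws[v] for v in bn.nodes})


def to_case_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Expand the categorical class node into the six indicator columns of
    the analysis case table (fixed column order)."""
    from .discretize import CASE_COLUMNS

    out = {}
    for i, cls in enumerate(AD_CLASSES):
        out[f"ad_{cls}"] = (cases[CLASS_NODE] == i).astype(np.int8)
    for c in BINARY_NODES:
        out[c] = cases[c].astype(np.int8)
    return pd.DataFrame(out)[list(CASE_COLUMNS)]


# ---------------------------------------------------------------------------
# rendering cases into raw EHR-style records
# ---------------------------------------------------------------------------

@dataclass
class RawCohort:
    """Raw event-level view of a cohort, as the pipeline would ingest it."""

    prescriptions: list[PrescriptionRecord]
    patients: pd.DataFrame          # patient_id, sex_female, age, dx_* flags
    gaf: pd.DataFrame               # patient_id, gaf (NaN when unrecorded)
    sentiment_events: list[SentimentEvent]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_prescriptions_csv(self.prescriptions, directory / "prescriptions.csv")
        self.patients.to_csv(directory / "patients.csv", index=False)
        self.gaf.to_csv(directory / "gaf.csv", index=False)
        write_sentiment_csv(self.sentiment_events, directory / "sentiment_events.csv")


#: mean detected change-sentences per theme per trajectory (reference cohort)
DEFAULT_EVENT_MEANS: dict[str, float] = {
    "core_complaints": 4.06, "social_functioning": 1.65,
    "well_being": 4.04, "experience": 5.69,
}


def render_ehr(cases: pd.DataFrame, seed: int,
               dose_table: DoseTable | None = None,
               corruption_rate: float = 0.0,
               gaf_missing_rate: float = 0.15,
               event_means: Mapping[str, float] = DEFAULT_EVENT_MEANS) -> RawCohort:
    """Render sampled cases into raw records the pipeline can rebuild.

    Each case becomes one patient whose first antidepressant trajectory has
    the case's class, an overall span of at least 35 days exactly when the
    duration node is 1 (possibly split into consecutive prescriptions with
    gaps of at most 30 days, which the builder must re-merge), co-medication
    prescriptions overlapping the trajectory exactly for the flags set, and
    per-theme sentiment events whose mean polarity sign matches the sentiment
    nodes.  A non-continued case gets a later prescription of a different
    class.  ``corruption_rate`` of the patients additionally receive one
    implausibly dosed prescription that the dose filter must remove.
    """
    if not 0.0 <= corruption_rate <= 1.0:
        raise ValueError("corruption_rate must lie in [0, 1]")
    if not 0.0 <= gaf_missing_rate <= 1.0:
        raise ValueError("gaf_missing_rate must lie in [0, 1]")
    dose_table = dose_table or DoseTable.default()
    rng = np.random.default_rng(seed)
    n = len(cases)

    prescriptions: list[PrescriptionRecord] = []
    patients_rows = []
    gaf_rows = []
    events: list[SentimentEvent] = []

    def _script(pid: str, category: str, start: int, end: int) -> PrescriptionRecord:
        drug = str(rng.choice(dose_table.drugs_in(category)))
        e = dose_table[drug]
        dose = round(float(rng.uniform(e.min_dose, e.max_dose)), 1)
        return PrescriptionRecord(pid, drug, dose, int(start), int(end))

    for i, row in enumerate(cases.itertuples(index=False)):
        case = dict(zip(cases.columns, row))
        pid = f"P{i:05d}"
        cls = AD_CLASSES[int(case[CLASS_NODE])]

        if case["duration_ge_5w"]:
            span = int(rng.integers(35, 301))
        else:
            span = int(rng.integers(2, 35))

        # split the trajectory into 1-3 consecutive scripts with gaps <= 30
        pieces = 1
        if span >= 120 and rng.random() < 0.5:
            pieces = 3
        elif span >= 50 and rng.random() < 0.5:
            pieces = 2
        cursor = 0
        segments = []
        remaining = span
        for k in range(pieces - 1):
            gap = int(rng.integers(1, 31))
            seg = int(rng.integers(5, max(6, (remaining - gap) // 2)))
            segments.append((cursor, cursor + seg))
            cursor += seg + gap
            remaining = span - cursor
        segments.append((cursor, span))
        for s, e in segments:
            prescriptions.append(_script(pid, cls, s, e))

        for comed in CO_MED_CLASSES:
            if case[comed]:
                s = int(rng.integers(0, span))
                e = s + int(rng.integers(1, 61))
                prescriptions.append(_script(pid, comed, s, e))

        if not case["continued"]:
            other = [c for c in AD_CLASSES if c != cls]
            cls2 = str(rng.choice(other))
            s2 = span + int(rng.integers(31, 121))
            prescriptions.append(_script(pid, cls2, s2, s2 + int(rng.integers(5, 61))))
        elif rng.random() < 0.3:
            # a pause within the same class: later same-class prescription,
            # which is *not* a switch
            s2 = span + int(rng.integers(31, 121))
            prescriptions.append(_script(pid, cls, s2, s2 + int(rng.integers(5, 61))))

        for theme in THEMES:
            k = int(rng.poisson(event_means[theme]))
            positive = bool(case[f"sent_{theme}"])
            if not positive and k == 0:
                k = 1
            if k == 0:
                continue
            half_up = math.ceil(k / 2)
            n_pos = (int(rng.integers(half_up, k + 1)) if positive
                     else int(rng.integers(0, half_up)))
            polarities = [1] * n_pos + [-1] * (k - n_pos)
            for pol in polarities:
                events.append(SentimentEvent(pid, theme,
                                             int(rng.integers(0, span + 1)), pol))

        age = int(rng.integers(48, 86)) if case["age_ge_48"] else int(rng.integers(18, 48))
        patients_rows.append({
            "patient_id": pid, "sex_female": int(case["sex_female"]), "age": age,
            **{d: int(case[d]) for d in DX_FLAGS}})
        gaf_rows.append({"patient_id": pid,
                         "gaf": (int(rng.integers(50, 71)) if case["gaf_ge_50"]
                                 else int(rng.integers(20, 50)))})

    # corrupt a fixed fraction of patients with one implausibly dosed record
    n_corrupt = round(corruption_rate * n)
    if n_corrupt:
        victims = rng.choice(n, size=n_corrupt, replace=False)
        all_drugs = sorted(d for c in AD_CLASSES + CO_MED_CLASSES
                           for d in dose_table.drugs_in(c))
        for v in victims:
            pid = f"P{int(v):05d}"
            drug = str(rng.choice(all_drugs))
            e = dose_table[drug]
            if rng.random() < 0.5:
                dose = round(0.5 * e.min_dose * float(rng.uniform(0.05, 0.9)), 2)
                dose = max(dose, 0.01)
            else:
                dose = round(5.0 * e.max_dose * float(rng.uniform(1.2, 3.0)), 2)
            s = int(rng.integers(0, 400))
            prescriptions.append(PrescriptionRecord(
                pid, drug, dose, s, s + int(rng.integers(1, 31))))

    # GAF missing completely at random at the configured exact fraction
    n_missing = round(gaf_missing_rate * n)
    gaf_df = pd.DataFrame(gaf_rows)
    if n_missing:
        idx = rng.choice(n, size=n_missing, replace=False)
        gaf_df.loc[idx, "gaf"] = np.nan

    return RawCohort(prescriptions, pd.DataFrame(patients_rows), gaf_df, events)


def write_ground_truth(bn: BayesianNetwork, directory: str | Path) -> None:
    """Persist the ground truth as DOT (structure) plus JSON (CPTs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ground_truth.dot").write_text(bn.dag.to_dot("ground_truth"))
    (directory / "ground_truth_cpts.json").write_text(bn.to_json())


def read_cohort(directory: str | Path) -> RawCohort:
    from .sentiment import read_sentiment_csv
    from .trajectories import read_prescriptions_csv

    directory = Path(directory)
    return RawCohort(
        read_prescriptions_csv(directory / "prescriptions.csv"),
        pd.read_csv(directory / "patients.csv"),
        pd.read_csv(directory / "gaf.csv"),
        read_sentiment_csv(directory / "sentiment_events.csv"),
    )
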