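"""Discrete Bayesian networks: CPTs, maximum-likelihood fitting, exact and
approximate conditional-probability queries.

A :class:`BayesianNetwork` couples a :class:`~adtraj.graphs.DAG` with one
conditional probability table per node.  Nodes may take any finite number of
levels (the treatment-class variable has six); the analysis case table is
all binary.  ``exact_query`` answers P(target = value | evidence) by variable
elimination and serves as the oracle for ``logic_sampling_query``, the
forward-sampling/rejection scheme used for hypothetical-patient predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .graphs import DAG

ROW_SUM_TOL = 1e-12


class ZeroEvidenceError(ValueError):
    """The conditioning event has probability zero; the query is undefined."""


class InsufficientAcceptanceError(RuntimeError):
    """Rejection sampling accepted no draws; raise rather than return 0."""


@dataclass
class CPT:
    """P(node | parents) as a (parent-configuration x level) row-stochastic table.

    Parent configurations are coded mixed-radix in ``parents`` order (first
    parent most significant), so row ``i`` corresponds to the assignment
    decoded by :meth:`config_of`.
    """

    node: str
    parents: tuple[str, ...]
    levels: tuple[Any, ...]
    parent_levels: tuple[tuple[Any, ...], ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.levels = tuple(self.levels)
        self.parent_levels = tuple(tuple(l) for l in self.parent_levels)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod([len(l) for l in self.parent_levels])) if self.parents else 1
        if self.table.shape != (q, len(self.levels)):
            raise ValueError(
                f"CPT for {self.node}: table shape {self.table.shape}, "
                f"expected ({q}, {len(self.levels)})")
        bad = np.abs(self.table.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            raise ValueError(f"CPT rows for {self.node} do not sum to 1")

    @property
    def n_configs(self) -> int:
        return self.table.shape[0]

    def config_index(self, assignment: Mapping[str, Any]) -> int:
        idx = 0
        for p, lv in zip(self.parents, self.parent_levels):
            idx = idx * len(lv) + lv.index(assignment[p])
        return idx

    def config_of(self, row: int) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for p, lv in zip(reversed(self.parents), reversed(self.parent_levels)):
            out[p] = lv[row % len(lv)]
            row //= len(lv)
        return {p: out[p] for p in self.parents}


@dataclass
class BayesianNetwork:
    dag: DAG
    cpts: dict[str, CPT]
    flagged_rows: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            if v not in self.cpts:
                raise ValueError(f"missing CPT for {v}")
            if self.cpts[v].parents != self.dag.parents(v):
                raise ValueError(
                    f"CPT parents for {v} ({self.cpts[v].parents}) do not "
                    f"match DAG parents ({self.dag.parents(v)})")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def levels(self, node: str) -> tuple[Any, ...]:
        return self.cpts[node].levels

    # -- sampling --------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Ancestral (forward) sample of ``n`` full assignments.

        Values are level *indices* (0..r-1); callers map them to labels.
        """
        out: dict[str, np.ndarray] = {}
        for v in self.dag.topological_order():
            cpt = self.cpts[v]
            if cpt.parents:
                codes = np.zeros(n, dtype=np.int64)
                for p, lv in zip(cpt.parents, cpt.parent_levels):
                    codes = codes * len(lv) + out[p]
                probs = cpt.table[codes]
            else:
                probs = np.broadcast_to(cpt.table[0], (n, len(cpt.levels)))
            u = rng.random(n)
            out[v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1).astype(np.int64)
        return out

    # -- io --------------------------------------------------------------
    def to_json(self) -> str:
        payload = {}
        for v in self.nodes:
            cpt = self.cpts[v]
            rows = {}
            for i in range(cpt.n_configs):
                key = ",".join(f"{p}={cpt.config_of(i)[p]}" for p in cpt.parents) or "-"
                rows[key] = {str(lv): cpt.table[i, j]
                             for j, lv in enumerate(cpt.levels)}
            payload[v] = {"parents": list(cpt.parents),
                          "levels": [str(l) for l in cpt.levels],
                          "table": rows}
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class Query:
    """A conditional-probability question about one hypothetical patient."""

    target: str
    value: Any = 1
    evidence: Mapping[str, Any] = field(default_factory=dict)
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target in self.evidence:
            raise ValueError("target may not appear in the evidence")


# ---------------------------------------------------------------------------
# parameter learning
# ---------------------------------------------------------------------------

def fit_mle(dag: DAG, data,
            levels: Mapping[str, Sequence[Any]] | None = None) -> BayesianNetwork:
    """Maximum-likelihood CPTs: conditional relative frequencies per node.

    Parent configurations never observed in the data get a uniform row and are
    recorded in ``flagged_rows`` so downstream queries can be audited.
    ``data`` columns must hold integer level indices (0/1 for the case table).
    """
    cols = {c: np.asarray(data[c], dtype=np.int64)
            for c in (data.columns if hasattr(data, "columns") else data.keys())}
    n = len(next(iter(cols.values())))
    cpts: dict[str, CPT] = {}
    flagged: dict[str, list[int]] = {}
    for v in dag.nodes:
        lv = tuple(levels[v]) if levels is not None else tuple(
            range(max(int(cols[v].max()) + 1, 2)))
        ps = dag.parents(v)
        plv = tuple(tuple(levels[p]) if levels is not None else tuple(
            range(max(int(cols[p].max()) + 1, 2))) for p in ps)
        q = int(np.prod([len(l) for l in plv])) if ps else 1
        code = np.zeros(n, dtype=np.int64)
        for p, l in zip(ps, plv):
            code = code * len(l) + cols[p]
        code = code * len(lv) + cols[v]
        counts = np.bincount(code, minlength=q * len(lv)).astype(float)
        table = counts.reshape(q, len(lv))
        totals = table.sum(axis=1)
        empty = np.flatnonzero(totals == 0)
        if empty.size:
            flagged[v] = empty.tolist()
            table[empty] = 1.0
            totals = table.sum(axis=1)
        table /= totals[:, None]
        cpts[v] = CPT(v, ps, lv, plv, table)
    return BayesianNetwork(dag, cpts, flagged)


# ---------------------------------------------------------------------------
# exact inference by variable elimination
# ---------------------------------------------------------------------------

def _level_index(cpt_levels: tuple[Any, ...], value: Any) -> int:
    if value in cpt_levels:
        return cpt_levels.index(value)
    raise KeyError(f"value {value!r} not among levels {cpt_levels}")


class _Factor:
    __slots__ = ("vars", "array")

    def __init__(self, vars: tuple[str, ...], array: np.ndarray):
        self.vars = vars
        self.array = array

    def multiply(self, other: "_Factor") -> "_Factor":
        all_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(all_vars)
        b = other._expand(all_vars)
        return _Factor(all_vars, a * b)

    def _expand(self, all_vars: tuple[str, ...]) -> np.ndarray:
        src = {v: i for i, v in enumerate(self.vars)}
        arr = self.array
        # append missing axes then transpose into position
        order = [src[v] for v in all_vars if v in src]
        arr = np.transpose(arr, order)
        shape = list(arr.shape)
        full_shape = []
        k = 0
        for v in all_vars:
            if v in src:
                full_shape.append(shape[k])
                k += 1
            else:
                full_shape.append(1)
        return arr.reshape(full_shape)

    def marginalize(self, var: str) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(self.vars[:i] + self.vars[i + 1:],
                       self.array.sum(axis=i))


def exact_query(bn: BayesianNetwork, query: Query) -> float:
    """P(target = value | evidence) by variable elimination; exact."""
    evidence = dict(query.evidence)
    factors: list[_Factor] = []
    for v in bn.nodes:
        cpt = bn.cpts[v]
        vars_ = cpt.parents + (v,)
        shape = [len(l) for l in cpt.parent_levels] + [len(cpt.levels)]
        arr = cpt.table.reshape(shape)
        f = _Factor(tuple(vars_), arr)
        for ev, val in evidence.items():
            if ev in f.vars:
                i = f.vars.index(ev)
                idx = _level_index(bn.levels(ev), val)
                f = _Factor(f.vars[:i] + f.vars[i + 1:],
                            np.take(f.array, idx, axis=i))
        factors.append(f)

    to_eliminate = [v for v in bn.nodes
                    if v != query.target and v not in evidence]
    while to_eliminate:
        # cheapest-first: eliminate the variable whose product factor is smallest
        def cost(v: str) -> int:
            vs = set()
            for f in factors:
                if v in f.vars:
                    vs |= set(f.vars)
            return len(vs)
        var = min(sorted(to_eliminate), key=cost)
        to_eliminate.remove(var)
        involved = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize(var))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    if result.vars != (query.target,):
        # target had evidence-free scalar factors only; expand explicitly
        result_arr = result.array.reshape(-1)
        if result_arr.size == 1:
            raise ValueError("target variable vanished during elimination")
        vec = result_arr
    else:
        vec = result.array
    total = float(vec.sum())
    if total <= 0.0:
        raise ZeroEvidenceError(f"evidence {evidence} has probability zero")
    idx = _level_index(bn.levels(query.target), query.value)
    return float(vec[idx] / total)


# ---------------------------------------------------------------------------
# logic (rejection) sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingEstimate:
    probability: float
    standard_error: float
    n_accepted: int


def logic_sampling_query(bn: BayesianNetwork, query: Query) -> SamplingEstimate:
    """Forward-sample full assignments, reject those contradicting the
    evidence, and estimate P(target = value | evidence) from the rest.

    Raises :class:`InsufficientAcceptanceError` when nothing is accepted —
    an explicit failure is safer than silently reporting zero.
    """
    if query.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(query.seed)
    draws = bn.sample(query.n_samples, rng)
    mask = np.ones(query.n_samples, dtype=bool)
    for ev, val in query.evidence.items():
        mask &= draws[ev] == _level_index(bn.levels(ev), val)
    n_acc = int(mask.sum())
    if n_acc == 0:
        raise InsufficientAcceptanceError(
            f"no forward samples consistent with evidence {dict(query.evidence)}")
    tidx = _level_index(bn.levels(query.target), query.value)
    hits = int((draws[query.target][mask] == tidx).sum())
    p = hits / n_acc
    se = math.sqrt(max(p * (1.0 - p), 0.0) / n_acc)
    return SamplingEstimate(p, se, n_acc)


def probability_delta(bn: BayesianNetwork, target: str, value: Any,
                      evidence_base: Mapping[str, Any],
                      evidence_alt: Mapping[str, Any]) -> float:
    """Change in P(target = value), alternative minus base evidence, in
    percentage points (the scale used to talk about hypothetical patients)."""
    p_alt = exact_query(bn, Query(target, value, dict(evidence_alt)))
    p_base = exact_query(bn, Query(target, value, dict(evidence_base)))
    return 100.0 * (p_alt - p_base)
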