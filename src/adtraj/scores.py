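"""Decomposable BIC score for discrete Bayesian networks.

Convention: score = log-likelihood  -  (log n / 2) * (number of free
parameters); larger is better.  The score decomposes into one local term per
node, so single-arc search moves only re-evaluate the node whose parent set
changed.  ``ScoreCache`` memoises local terms by (node, parent set), which is
what makes tabu search and exhaustive enumeration on small node sets cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphs import DAG


@dataclass(frozen=True)
class Score:
    """Per-node local BIC terms; ``total`` is their sum (log-units)."""

    local: dict[str, float]
    total: float


class ScoreCache:
    """Memoised local BIC terms for one dataset.

    The dataset is frozen at construction (columns coded 0..card-1).  Local
    terms are keyed by (node, sorted parent tuple).
    """

    def __init__(self, data):
        self.columns: tuple[str, ...] = tuple(data.columns) if hasattr(
            data, "columns") else tuple(data.keys())
        self._x = {c: np.ascontiguousarray(np.asarray(data[c], dtype=np.int64))
                   for c in self.columns}
        self.n = len(next(iter(self._x.values()))) if self.columns else 0
        self._cards = {c: max(int(v.max()) + 1, 2) if self.n else 2
                       for c, v in self._x.items()}
        self._log_n = math.log(self.n) if self.n else 0.0
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def cardinality(self, node: str) -> int:
        return self._cards[node]

    def local_score(self, node: str, parents: tuple[str, ...]) -> float:
        parents = tuple(sorted(parents))
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached

        r = self._cards[node]
        q = 1
        code = np.zeros(self.n, dtype=np.int64)
        for p in parents:
            code = code * self._cards[p] + self._x[p]
            q *= self._cards[p]
        code = code * r + self._x[node]
        counts = np.bincount(code, minlength=q * r).astype(float).reshape(q, r)
        n_config = counts.sum(axis=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0,
                          counts * np.log(counts / n_config[:, None]), 0.0)
        value = float(ll.sum()) - 0.5 * self._log_n * q * (r - 1)
        self._cache[key] = value
        return value

    def score(self, dag: DAG) -> Score:
        local = {v: self.local_score(v, dag.parents(v)) for v in dag.nodes}
        return Score(local, sum(local.values()))


def bic_score(dag: DAG, data) -> Score:
    """BIC of ``dag`` on complete discrete ``data`` (larger is better)."""
    missing = [v for v in dag.nodes if v not in set(
        data.columns if hasattr(data, "columns") else data.keys())]
    if missing:
        raise KeyError(f"dag nodes absent from data: {missing}")
    return ScoreCache(data).score(dag)
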