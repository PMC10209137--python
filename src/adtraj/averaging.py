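"""Bootstrap model averaging of learned structures.

A single learned network is noisy; resampling the cases with replacement,
re-learning on each resample and keeping only edges that appear in more than
a strength threshold (default 85%) of the resamples yields the averaged
network actually interpreted.  ``ArcStrengthTable`` records, per node pair,
the fraction of bootstrap networks containing the edge in either orientation
(*strength*) and, among those, the fraction orienting it each way
(*direction*); undirected CPDAG edges contribute half to each direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .graphs import CPDAG, DAG
from .pc import pc_stable
from .tabu import tabu_search

log = logging.getLogger(__name__)

STRENGTH_THRESHOLD = 0.85  # edges must appear in more than 85% of resamples


@dataclass
class ArcStrengthTable:
    """Edge strengths and orientation preferences over one bootstrap run."""

    nodes: tuple[str, ...]
    strength: dict[tuple[str, str], float]    # symmetric in the pair
    direction: dict[tuple[str, str], float]   # direction(a,b)+direction(b,a)=1
    n_replicates: int

    def pairs(self):
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                yield (a, b)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"from": a, "to": b,
                 "strength": self.strength.get((a, b), 0.0),
                 "direction": self.direction.get((a, b), 0.0)}
                for a in self.nodes for b in self.nodes if a != b]
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _learner(name_or_fn) -> Callable:
    if callable(name_or_fn):
        return name_or_fn
    if name_or_fn == "pc_stable":
        return lambda d, seed: pc_stable(d).cpdag
    if name_or_fn == "tabu":
        return lambda d, seed: tabu_search(d, seed=seed)
    raise ValueError(f"unknown learner {name_or_fn!r}")


def bootstrap_arcs(data, learner, R: int = 100, seed: int = 0,
                   max_retries: int = 3) -> ArcStrengthTable:
    """Tally edge occurrence over ``R`` nonparametric bootstrap resamples.

    ``learner`` is ``"pc_stable"``, ``"tabu"`` or a callable
    ``(data, seed) -> DAG | CPDAG``.  Resamples draw n rows with replacement
    at full n.  A learner failure on a resample is logged and the resample
    redrawn, at most ``max_retries`` times each.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    fn = _learner(learner)
    nodes = tuple(data.columns) if hasattr(data, "columns") else tuple(data.keys())
    n = len(data[nodes[0]])
    rng = np.random.default_rng(seed)

    edge_counts: dict[tuple[str, str], float] = {}
    dir_counts: dict[tuple[str, str], float] = {}

    def tally(a: str, b: str, weight_ab: float, weight_ba: float) -> None:
        key = tuple(sorted((a, b)))
        edge_counts[key] = edge_counts.get(key, 0.0) + 1.0
        dir_counts[(a, b)] = dir_counts.get((a, b), 0.0) + weight_ab
        dir_counts[(b, a)] = dir_counts.get((b, a), 0.0) + weight_ba

    for r in range(R):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            resample = (data.iloc[idx].reset_index(drop=True)
                        if hasattr(data, "iloc")
                        else {c: np.asarray(data[c])[idx] for c in nodes})
            try:
                net = fn(resample, int(rng.integers(2 ** 31)))
                break
            except Exception:                     # noqa: BLE001 - redraw
                log.warning("learner failed on bootstrap replicate %d "
                            "(attempt %d); redrawing", r, attempt + 1,
                            exc_info=True)
        else:
            raise RuntimeError(f"learner kept failing on replicate {r}")
        if isinstance(net, DAG):
            for a, b in net.arcs:
                tally(a, b, 1.0, 0.0)
        elif isinstance(net, CPDAG):
            for a, b in net.arcs:
                tally(a, b, 1.0, 0.0)
            for a, b in net.edges:
                tally(a, b, 0.5, 0.5)
        else:
            raise TypeError(f"learner returned {type(net).__name__}")

    strength = {}
    direction = {}
    for (a, b), c in edge_counts.items():
        strength[(a, b)] = strength[(b, a)] = c / R
        direction[(a, b)] = dir_counts.get((a, b), 0.0) / c
        direction[(b, a)] = dir_counts.get((b, a), 0.0) / c
    return ArcStrengthTable(nodes, strength, direction, R)


def averaged_network(strengths: ArcStrengthTable,
                     threshold: float = STRENGTH_THRESHOLD) -> CPDAG:
    """Keep edges whose strength strictly exceeds ``threshold``; orient each
    by its direction majority, leaving exact 50/50 ties undirected.

    Monotone in the threshold: raising it never adds an edge.  In the rare
    event the majority orientations form a directed cycle, the cycle arcs
    with the weakest direction majority are demoted to undirected.
    """
    arcs: set[tuple[str, str]] = set()
    edges: set[tuple[str, str]] = set()
    for a, b in strengths.pairs():
        s = strengths.strength.get((a, b), 0.0)
        if s > threshold:
            d_ab = strengths.direction.get((a, b), 0.5)
            if d_ab > 0.5:
                arcs.add((a, b))
            elif d_ab < 0.5:
                arcs.add((b, a))
            else:
                edges.add((a, b))
    while True:
        try:
            return CPDAG(strengths.nodes, frozenset(arcs), frozenset(edges))
        except Exception:
            weakest = min(arcs, key=lambda ab: (
                abs(strengths.direction.get(ab, 0.5) - 0.5), ab))
            warnings.warn(f"direction majorities formed a cycle; demoting "
                          f"{weakest} to undirected")
            arcs.discard(weakest)
            edges.add(tuple(sorted(weakest)))


def _as_cpdag_parts(net: DAG | CPDAG):
    if isinstance(net, DAG):
        return frozenset(net.arcs), frozenset()
    return net.arcs, net.edges


def compare_networks(net_a: DAG | CPDAG, net_b: DAG | CPDAG) -> dict:
    """Overlap report between two structures on the same node set.

    Skeleton-shared edges ignore direction (the way cross-site overlap is
    usually counted); direction-agreeing shared edges require the same arc or
    both undirected; SHD is the structural Hamming distance between the two
    partially directed graphs.
    """
    na, nb = set(net_a.nodes), set(net_b.nodes)
    if na != nb:
        raise ValueError(f"node sets differ: only in A {sorted(na - nb)}, "
                         f"only in B {sorted(nb - na)}")
    arcs_a, edges_a = _as_cpdag_parts(net_a)
    arcs_b, edges_b = _as_cpdag_parts(net_b)
    skel_a = {tuple(sorted(e)) for e in arcs_a} | edges_a
    skel_b = {tuple(sorted(e)) for e in arcs_b} | edges_b
    shared = skel_a & skel_b

    agreeing = 0
    for e in shared:
        a, b = e
        type_a = ("u" if e in edges_a else ("f" if (a, b) in arcs_a else "r"))
        type_b = ("u" if e in edges_b else ("f" if (a, b) in arcs_b else "r"))
        agreeing += type_a == type_b

    shd = len(skel_a ^ skel_b)
    for e in shared:
        a, b = e
        type_a = ("u" if e in edges_a else ("f" if (a, b) in arcs_a else "r"))
        type_b = ("u" if e in edges_b else ("f" if (a, b) in arcs_b else "r"))
        shd += type_a != type_b

    return {
        "n_edges_a": len(skel_a),
        "n_edges_b": len(skel_b),
        "skeleton_shared": len(shared),
        "direction_agreeing": agreeing,
        "shd": shd,
    }
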