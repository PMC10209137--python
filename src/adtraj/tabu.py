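"""Score-based structure learning: greedy hill climbing with a tabu list.

Single-arc moves (add / delete / reverse) are scored by their BIC delta,
which touches only the endpoint whose parent set changes.  When no move
improves the current score, the best non-improving move not on the tabu list
is taken instead, and recently deleted or reversed arcs stay forbidden for
``tabu_length`` moves — the classic device for sliding out of local optima.
The best DAG ever visited is returned.
"""

from __future__ import annotations

import numpy as np

from .graphs import DAG
from .scores import ScoreCache


def _reachability(nodes, parents) -> dict[str, set[str]]:
    """For each node, the set of its ancestors (excluding itself)."""
    anc: dict[str, set[str]] = {}

    def visit(v: str) -> set[str]:
        if v in anc:
            return anc[v]
        anc[v] = set()  # placeholder guards against revisits mid-walk
        acc: set[str] = set()
        for p in parents[v]:
            acc.add(p)
            acc |= visit(p)
        anc[v] = acc
        return acc

    for v in nodes:
        visit(v)
    return anc


def _candidate_moves(nodes, parents, ancestors):
    """Yield (kind, a, b) for every legal single-arc move, in a fixed order."""
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            if a in parents[b]:
                yield ("delete", a, b)
                # reversing a->b is legal unless another path a ~> b remains
                if not any(a == anc or a in ancestors[anc]
                           for anc in parents[b] if anc != a):
                    yield ("reverse", a, b)
            elif b not in ancestors[a] and a not in parents[b]:
                yield ("add", a, b)


def hill_climb(data, seed: int = 0, max_iter: int = 10_000,
               start: DAG | None = None) -> DAG:
    """Plain greedy hill climbing (tabu machinery disabled)."""
    return tabu_search(data, tabu_length=0, max_no_improve=0, seed=seed,
                       max_iter=max_iter, start=start)


def tabu_search(data, tabu_length: int = 10, max_no_improve: int = 10,
                seed: int = 0, max_iter: int = 10_000,
                start: DAG | None = None) -> DAG:
    """Maximise BIC over DAGs on the data's columns; returns the best visited.

    Ties between equally scoring moves are broken by a seeded draw so runs
    are reproducible.  ``tabu_length`` counts moves during which a deleted or
    reversed arc may not be re-added / re-reversed; ``max_no_improve`` is the
    number of consecutive accepted moves that may fail to improve the *best*
    score seen before the search stops.
    """
    cache = ScoreCache(data)
    nodes = cache.columns
    rng = np.random.default_rng(seed)

    dag = start.copy() if start is not None else DAG(nodes)
    parents = {v: set(dag.parents(v)) for v in nodes}

    def local(v):
        return cache.local_score(v, tuple(parents[v]))

    current = sum(local(v) for v in nodes)
    best_dag, best_score = dag.copy(), current
    # move -> iteration index until which it is forbidden; the *inverse* of an
    # accepted move is tabu'd, so recently deleted / reversed arcs cannot come
    # straight back (and fresh additions cannot be undone immediately)
    tabu: dict[tuple[str, str, str], int] = {}
    no_improve = 0
    eps = 1e-9
    plain = tabu_length == 0 and max_no_improve == 0

    for it in range(max_iter):
        ancestors = _reachability(nodes, parents)
        moves = []
        for kind, a, b in _candidate_moves(nodes, parents, ancestors):
            if kind == "add":
                delta = (cache.local_score(b, tuple(parents[b] | {a}))
                         - local(b))
            elif kind == "delete":
                delta = (cache.local_score(b, tuple(parents[b] - {a}))
                         - local(b))
            else:  # reverse a->b
                delta = (cache.local_score(b, tuple(parents[b] - {a}))
                         - local(b)
                         + cache.local_score(a, tuple(parents[a] | {b}))
                         - local(a))
            # aspiration: a tabu move is still allowed if it beats the best
            # score seen so far
            if tabu.get((kind, a, b), -1) > it and current + delta <= best_score + eps:
                continue
            moves.append((delta, kind, a, b))
        if not moves:
            break

        deltas = np.array([m[0] for m in moves])
        top = deltas.max()
        idx = np.flatnonzero(deltas >= top - eps)
        choice = moves[int(rng.choice(idx))]
        if plain and choice[0] <= eps:
            break  # greedy hill climbing stops at the first local optimum

        delta, kind, a, b = choice
        if kind == "add":
            parents[b].add(a)
            inverse = ("delete", a, b)
        elif kind == "delete":
            parents[b].discard(a)
            inverse = ("add", a, b)
        else:
            parents[b].discard(a)
            parents[a].add(b)
            inverse = ("reverse", b, a)
        if not plain:
            tabu[inverse] = it + 1 + tabu_length
        current += delta
        if current > best_score + eps:
            best_score = current
            best_dag = DAG(nodes, [(p, v) for v in nodes for p in parents[v]])
            no_improve = 0
        else:
            # counted against the best score seen, so oscillations around a
            # local optimum cannot keep the search alive indefinitely
            no_improve += 1
            if not plain and no_improve > max_no_improve:
                break

    return best_dag
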