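"""PC-stable: order-independent constraint-based structure learning.

The skeleton phase tests each adjacent pair against conditioning subsets of
growing size drawn from the neighbourhoods *frozen at the start of each size
level*, which removes the order-dependence of classic PC.  Unshielded triples
whose middle node is absent from the recorded separating set become
v-structures; Meek rules close the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .citest import g2_test
from .graphs import CPDAG, _apply_meek, _find_cycle


@dataclass
class PCResult:
    cpdag: CPDAG
    sepsets: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    n_tests: int = 0
    n_degenerate: int = 0


def pc_stable(data, alpha: float = 0.05,
              max_cond_size: int | None = None) -> PCResult:
    """Learn a CPDAG from complete discrete data at significance ``alpha``.

    ``max_cond_size`` caps the conditioning-set size; by default it is
    unbounded and sparse tables cut the search off naturally (tests whose
    tables are too sparse are degenerate, hence non-rejections, so edges are
    retained rather than spuriously removed — but a degenerate test also
    cannot *remove* an edge, which is what terminates growth).
    """
    nodes = tuple(data.columns) if hasattr(data, "columns") else tuple(data.keys())
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: dict[tuple[str, str], tuple[str, ...]] = {}
    n_tests = n_degenerate = 0

    level = 0
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        frozen = {v: frozenset(adj[v]) for v in nodes}   # the "stable" freeze
        if not any(len(frozen[v]) - 1 >= level for v in nodes):
            break
        n_rows = len(data[nodes[0]])
        if n_rows < 5.0 * 4 * 2 ** level:
            # every test at this level would be degenerate (too few rows per
            # cell even for all-binary variables): nothing can be removed
            break
        for x in nodes:
            for y in sorted(frozen[x]):
                if x >= y or y not in adj[x]:
                    continue
                removed = False
                for (a, b) in ((x, y), (y, x)):
                    pool = sorted(frozen[a] - {b})
                    if len(pool) < level:
                        continue
                    for cond in combinations(pool, level):
                        res = g2_test(data, a, b, cond)
                        n_tests += 1
                        n_degenerate += res.degenerate
                        if not res.degenerate and res.p_value > alpha:
                            adj[x].discard(y)
                            adj[y].discard(x)
                            sepsets[(x, y)] = sepsets[(y, x)] = tuple(cond)
                            removed = True
                            break
                    if removed:
                        break
        level += 1

    # orient v-structures: unshielded x - c - y with c not in sepset(x, y)
    directed: set[tuple[str, str]] = set()
    for c in nodes:
        for x, y in combinations(sorted(adj[c]), 2):
            if y in adj[x]:
                continue
            if c not in sepsets.get((x, y), ()):
                for a in (x, y):
                    if (c, a) not in directed:
                        directed.add((a, c))

    # drop accidental two-way orientations from conflicting triples
    conflicts = {(a, b) for (a, b) in directed if (b, a) in directed}
    directed -= conflicts
    undirected = {tuple(sorted((a, b))) for a in nodes for b in adj[a] if a < b}
    undirected -= {tuple(sorted(e)) for e in directed}
    undirected |= {tuple(sorted(e)) for e in conflicts}

    _apply_meek(nodes, directed, undirected)

    # with finite data, conflicting v-structures can leave a directed cycle;
    # demote arcs on cycles to undirected until the directed part is acyclic
    while True:
        children: dict[str, set[str]] = {v: set() for v in nodes}
        for a, b in directed:
            children[a].add(b)
        cyc = _find_cycle(nodes, children)
        if cyc is None:
            break
        worst = max(zip(cyc, cyc[1:] + cyc[:1]))
        directed.discard(worst)
        undirected.add(tuple(sorted(worst)))

    cpdag = CPDAG(nodes, frozenset(directed), frozenset(undirected))
    return PCResult(cpdag, sepsets, n_tests, n_degenerate)
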