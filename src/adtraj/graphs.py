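"""Directed and partially directed acyclic graphs for discrete Bayesian networks.

``DAG`` is the substrate of score-based search and of fitted networks;
``CPDAG`` (completed partially directed acyclic graph) is the canonical
representative of a Markov-equivalence class, produced by constraint-based
learning and by :func:`cpdag_of`.  Both keep their node set in a fixed order
and iterate deterministically so that learned structures, DOT exports and
bootstrap tallies are reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class CycleError(ValueError):
    """Raised when an operation would create (or a spec contains) a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("cycle: " + " -> ".join(self.cycle + [self.cycle[0]]))


def _find_cycle(nodes: Iterable[str], children: dict[str, set[str]]) -> list[str] | None:
    """Return one directed cycle as a node list, or None if acyclic."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in nodes}
    stack: list[str] = []

    def visit(v: str) -> list[str] | None:
        color[v] = GREY
        stack.append(v)
        for w in sorted(children.get(v, ())):
            if color[w] == GREY:
                return stack[stack.index(w):]
            if color[w] == WHITE:
                cyc = visit(w)
                if cyc is not None:
                    return cyc
        stack.pop()
        color[v] = BLACK
        return None

    for v in sorted(color):
        if color[v] == WHITE:
            cyc = visit(v)
            if cyc is not None:
                return cyc
    return None


class DAG:
    """A labelled directed acyclic graph with mutation-time acyclicity checks."""

    def __init__(self, nodes: Iterable[str], arcs: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in arcs:
            self.add_arc(a, b, _check=False)
        cyc = _find_cycle(self.nodes, self._children)
        if cyc is not None:
            raise CycleError(cyc)

    # -- queries ---------------------------------------------------------
    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[v]))

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(self._children[v]))

    @property
    def arcs(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted((a, b) for b in self.nodes for a in self._parents[b]))

    def has_arc(self, a: str, b: str) -> bool:
        return a in self._parents[b]

    def has_path(self, a: str, b: str) -> bool:
        """True iff a directed path a ~> b exists (a == b counts)."""
        if a == b:
            return True
        seen = {a}
        frontier = deque([a])
        while frontier:
            v = frontier.popleft()
            for w in self._children[v]:
                if w == b:
                    return True
                if w not in seen:
                    seen.add(w)
                    frontier.append(w)
        return False

    def topological_order(self) -> list[str]:
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        ready = sorted(v for v, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            v = ready.pop(0)
            order.append(v)
            for w in sorted(self._children[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    # keep 'ready' sorted for deterministic output
                    ready.append(w)
                    ready.sort()
        if len(order) != len(self.nodes):
            raise CycleError(_find_cycle(self.nodes, self._children) or [])
        return order

    # -- mutation --------------------------------------------------------
    def add_arc(self, a: str, b: str, _check: bool = True) -> None:
        if a == b:
            raise ValueError(f"self-loop {a}->{a}")
        if a not in self._parents or b not in self._parents:
            raise KeyError(f"unknown node in arc {a}->{b}")
        if a in self._parents[b]:
            raise ValueError(f"duplicate arc {a}->{b}")
        if _check and self.has_path(b, a):
            raise CycleError([a, b])
        self._parents[b].add(a)
        self._children[a].add(b)

    def remove_arc(self, a: str, b: str) -> None:
        self._parents[b].discard(a)
        self._children[a].discard(b)

    def copy(self) -> "DAG":
        return DAG(self.nodes, self.arcs)

    # -- comparison / io -------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return (isinstance(other, DAG) and self.nodes == other.nodes
                and self.arcs == other.arcs)

    def __hash__(self) -> int:
        return hash((self.nodes, self.arcs))

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.arcs)} arcs)"

    def to_dot(self, name: str = "dag") -> str:
        lines = [f"digraph {name} {{"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for a, b in self.arcs:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class CPDAG:
    """Partially directed graph: compelled arcs plus reversible undirected edges.

    ``arcs`` hold the compelled (directed) part; ``edges`` the undirected part
    as sorted node pairs.  The directed part must be acyclic and no pair may be
    simultaneously directed and undirected.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.arcs = frozenset(self.arcs)
        self.edges = frozenset(tuple(sorted(e)) for e in self.edges)
        for a, b in self.arcs:
            if tuple(sorted((a, b))) in self.edges:
                raise ValueError(f"{a}-{b} both directed and undirected")
        children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.arcs:
            children[a].add(b)
        cyc = _find_cycle(self.nodes, children)
        if cyc is not None:
            raise CycleError(cyc)

    @property
    def skeleton(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.arcs) | self.edges

    def adjacent(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.skeleton

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, CPDAG) and set(self.nodes) == set(other.nodes)
                and self.arcs == other.arcs and self.edges == other.edges)

    def to_dot(self, name: str = "cpdag") -> str:
        lines = [f"digraph {name} {{"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for a, b in sorted(self.arcs):
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in sorted(self.edges):
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Meek orientation rules and DAG -> CPDAG conversion
# ---------------------------------------------------------------------------

def _apply_meek(nodes: Sequence[str], directed: set[tuple[str, str]],
                undirected: set[tuple[str, str]]) -> None:
    """Orient undirected edges in place using Meek rules R1-R4 to closure."""
    def adjacent(a: str, b: str) -> bool:
        return ((a, b) in directed or (b, a) in directed
                or tuple(sorted((a, b))) in undirected)

    def orient(a: str, b: str) -> bool:
        e = tuple(sorted((a, b)))
        if e in undirected and (b, a) not in directed:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected):
            for b, c in (e, e[::-1]):
                # R1: a -> b, b - c, a and c non-adjacent  =>  b -> c
                if any(a != c and not adjacent(a, c)
                       for (a, bb) in directed if bb == b):
                    if orient(b, c):
                        changed = True
                        break
                # R2: b -> k -> c and b - c  =>  b -> c
                if any((b, k) in directed and (k, c) in directed
                       for k in nodes):
                    if orient(b, c):
                        changed = True
                        break
                # R3: b - a1, b - a2, a1 -> c, a2 -> c, a1/a2 non-adjacent,
                #     b - c  =>  b -> c
                spouses = [a for a in nodes
                           if (a, c) in directed
                           and tuple(sorted((a, b))) in undirected]
                if any(not adjacent(a1, a2)
                       for i, a1 in enumerate(spouses)
                       for a2 in spouses[i + 1:]):
                    if orient(b, c):
                        changed = True
                        break
                # R4 (needed only with background knowledge) is omitted.
            if changed:
                break


def cpdag_of(dag: DAG) -> CPDAG:
    """Markov-equivalence-class representative of ``dag``.

    Compelled arcs (those shared by every equivalent DAG) stay directed;
    reversible arcs become undirected edges.  Computed by keeping the
    v-structures of ``dag`` directed and closing under the Meek rules.
    """
    adj: dict[str, set[str]] = {v: set() for v in dag.nodes}
    for a, b in dag.arcs:
        adj[a].add(b)
        adj[b].add(a)

    directed: set[tuple[str, str]] = set()
    for c in dag.nodes:
        ps = dag.parents(c)
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                if b not in adj[a]:           # unshielded collider a -> c <- b
                    directed.add((a, c))
                    directed.add((b, c))
    undirected = {tuple(sorted((a, b))) for a, b in dag.arcs
                  if (a, b) not in directed}
    _apply_meek(dag.nodes, directed, undirected)
    return CPDAG(dag.nodes, frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------

def d_separated(dag: DAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is blocked given ``z``.

    Chains and forks are blocked when their middle node is in ``z``;
    colliders are blocked unless the collider or one of its descendants is
    in ``z``.  Implemented as reachability over (node, incoming-direction)
    states (the Bayes-ball scheme).
    """
    zs = set(z)
    for v in (x, y, *zs):
        if v not in dag._parents:
            raise KeyError(f"unknown node {v!r}")
    if x == y:
        raise ValueError("x and y must differ")

    # nodes with a descendant (or themselves) in z: colliders open on these
    opens_collider: set[str] = set()
    frontier = deque(zs)
    opens_collider.update(zs)
    while frontier:
        v = frontier.popleft()
        for p in dag._parents[v]:
            if p not in opens_collider:
                opens_collider.add(p)
                frontier.append(p)

    # state: (node, came_from_child) — True means we arrived via an arc
    # pointing *into* this node's children side (moving against arrows).
    start = [(x, False), (x, True)]
    seen: set[tuple[str, bool]] = set(start)
    queue = deque(start)
    while queue:
        v, up = queue.popleft()
        if v == y and v not in zs:
            return False
        if up:  # arrived moving child -> parent (against the arrow at v)
            if v not in zs:
                nexts: list[tuple[str, bool]] = (
                    [(p, True) for p in dag._parents[v]]
                    + [(c, False) for c in dag._children[v]])
            else:
                nexts = []
        else:   # arrived moving parent -> child (along the arrow into v)
            nexts = []
            if v not in zs:
                nexts += [(c, False) for c in dag._children[v]]
            if v in opens_collider:
                nexts += [(p, True) for p in dag._parents[v]]
        for s in nexts:
            if s not in seen and s[0] != x:
                seen.add(s)
                queue.append(s)
    return True


# ---------------------------------------------------------------------------
# arc-list CSV round trip
# ---------------------------------------------------------------------------

def write_arc_csv(graph: DAG | CPDAG, path) -> None:
    """Write ``from,to,directed`` rows; undirected CPDAG edges once, flag 0."""
    with open(path, "w") as fh:
        fh.write("from,to,directed\n")
        if isinstance(graph, DAG):
            for a, b in graph.arcs:
                fh.write(f"{a},{b},1\n")
        else:
            for a, b in sorted(graph.arcs):
                fh.write(f"{a},{b},1\n")
            for a, b in sorted(graph.edges):
                fh.write(f"{a},{b},0\n")


def read_arc_csv(path, nodes: Iterable[str]) -> CPDAG:
    arcs, edges = set(), set()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "from,to,directed":
            raise ValueError(f"unexpected header {header!r}")
        for line in fh:
            a, b, d = line.strip().split(",")
            (arcs if d == "1" else edges).add((a, b))
    return CPDAG(tuple(nodes), frozenset(arcs), frozenset(edges))
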