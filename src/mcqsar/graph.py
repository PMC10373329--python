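"""Hydrogen-suppressed molecular graph and its vertex invariants.

The graph side of the hybrid descriptor works on the heavy-atom graph built
directly from the SMILES string.  For every vertex we compute three pairs of
classic topological invariants:

* Morgan extended connectivity of orders 1 and 2 (order 0 is the degree,
  order k sums the neighbours' order k-1 values);
* counts of simple paths of exactly 2 and 3 edges starting at the vertex;
* valence shells: the number of vertices at shortest-path distance exactly
  2 and exactly 3.

Each invariant value becomes an element-tagged attribute key, together with
the sum and absolute difference of each pair, plus ring codes for 5- and
6-membered rings (aromaticity and heteroatom presence, with the ring count
in the payload).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx

from .keys import AttributeKey, EC, PT, SHELL, COMBO, RING
from .smiles import SmilesError, Token, tokenize, is_atom_token

_BOND_ORDER = {"=": 2, "#": 3}


@dataclass
class MolecularGraph:
    """Simple undirected heavy-atom graph."""

    elements: list[str] = field(default_factory=list)   # as written: 'c' vs 'C'
    aromatic: list[bool] = field(default_factory=list)
    edges: list[tuple[int, int, object]] = field(default_factory=list)
    adjacency: list[list[int]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.elements)

    def add_vertex(self, element: str) -> int:
        self.elements.append(element)
        self.aromatic.append(element[0].islower())
        self.adjacency.append([])
        return len(self.elements) - 1

    def add_edge(self, u: int, v: int, order: object) -> None:
        if u == v:
            raise SmilesError("self-loop in molecular graph")
        if v in self.adjacency[u]:
            raise SmilesError(f"duplicate bond between atoms {u} and {v}")
        self.edges.append((u, v, order))
        self.adjacency[u].append(v)
        self.adjacency[v].append(u)

    def rings(self) -> list[list[int]]:
        """Smallest set of smallest rings (minimum cycle basis)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from((u, v) for u, v, _ in self.edges)
        return [sorted(c) for c in nx.minimum_cycle_basis(g)]


def build_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string of the supported dialect into a graph.

    Ring-closure digits become edges; branches follow parenthesis nesting;
    an explicit ``=`` or ``#`` before an atom or ring digit sets the bond
    order; a bond between two aromatic atoms with no explicit mark is
    recorded as aromatic.
    """
    tokens = tokenize(smiles)
    graph = MolecularGraph()
    prev: int | None = None
    pending_order: object = None
    stack: list[int | None] = []
    open_rings: dict[str, tuple[int, object]] = {}

    def bond_order(u: int, v: int, explicit: object) -> object:
        if explicit is not None:
            return explicit
        if graph.aromatic[u] and graph.aromatic[v]:
            return "ar"
        return 1

    for tok in tokens:
        text = tok.text
        if is_atom_token(text):
            idx = graph.add_vertex(text)
            if prev is not None:
                graph.add_edge(prev, idx, bond_order(prev, idx, pending_order))
            pending_order = None
            prev = idx
        elif text in _BOND_ORDER:
            pending_order = _BOND_ORDER[text]
        elif text == "@":
            continue  # stereo mark: no graph consequence
        elif text == "(":
            stack.append(prev)
        elif text == ")":
            if not stack:
                raise SmilesError(f"unbalanced ')' at position {tok.position}")
            prev = stack.pop()
            pending_order = None
        else:  # ring-closure digit
            if prev is None:
                raise SmilesError(f"ring closure before any atom at position {tok.position}")
            if text in open_rings:
                other, order0 = open_rings.pop(text)
                explicit = pending_order if pending_order is not None else order0
                graph.add_edge(prev, other, bond_order(prev, other, explicit))
                pending_order = None
            else:
                open_rings[text] = (prev, pending_order)
                pending_order = None
    if stack:
        raise SmilesError("unbalanced '(' in SMILES")
    if open_rings:
        digit = next(iter(open_rings))
        raise SmilesError(f"unmatched ring-closure digit {digit!r}")
    return graph


def morgan_ec(graph: MolecularGraph, order: int) -> list[int]:
    """Morgan extended connectivity of the given order for every vertex."""
    if order < 0:
        raise ValueError("order must be >= 0")
    values = [len(nbrs) for nbrs in graph.adjacency]
    for _ in range(order):
        values = [sum(values[u] for u in nbrs) for nbrs in graph.adjacency]
    return values


def path_counts(graph: MolecularGraph, length: int) -> list[int]:
    """Simple paths (no repeated vertex) of exactly `length` edges per start vertex."""
    if length < 1:
        raise ValueError("length must be >= 1")
    counts = [0] * graph.n_vertices
    for start in range(graph.n_vertices):
        # DFS over vertex-disjoint walks of fixed depth
        stack = [(start, 1, {start})]
        total = 0
        while stack:
            v, depth, seen = stack.pop()
            for u in graph.adjacency[v]:
                if u in seen:
                    continue
                if depth == length:
                    total += 1
                else:
                    stack.append((u, depth + 1, seen | {u}))
        counts[start] = total
    return counts


def valence_shells(graph: MolecularGraph, radius: int) -> list[int]:
    """Vertices at shortest-path distance exactly `radius` from each vertex."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    counts = [0] * graph.n_vertices
    for start in range(graph.n_vertices):
        dist = {start: 0}
        queue = deque([start])
        hits = 0
        while queue:
            v = queue.popleft()
            if dist[v] == radius:
                hits += 1
                continue  # no need to expand past the shell
            for u in graph.adjacency[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        counts[start] = hits
    return counts


def ring_codes(graph: MolecularGraph) -> Counter[AttributeKey]:
    """Ring-class keys for 5- and 6-membered rings.

    A ring class is (size, aromatic, heteroatom presence); the payload also
    carries how many rings of the class the molecule contains, so molecules
    differing only in ring count get distinct keys.
    """
    classes: Counter[tuple[int, bool, bool]] = Counter()
    for ring in graph.rings():
        size = len(ring)
        if size not in (5, 6):
            continue
        aromatic = all(graph.aromatic[v] for v in ring)
        hetero = any(graph.elements[v].upper() not in ("C",) for v in ring)
        classes[(size, aromatic, hetero)] += 1
    counts: Counter[AttributeKey] = Counter()
    for (size, aromatic, hetero), n in classes.items():
        payload = f"{size}|ar={int(aromatic)}|het={int(hetero)}|n={n}"
        counts[AttributeKey(RING, payload)] = 1
    return counts


def graph_attributes(graph: MolecularGraph, ec_orders: tuple[int, int] = (1, 2)) -> Counter[AttributeKey]:
    """All graph-side attributes of one molecule.

    Per vertex: the two EC orders, pt2/pt3, s2/s3, and the sum and absolute
    difference of each pair, every payload tagged with the element symbol as
    written (aromatic lowercase stays lowercase).  Plus the ring codes.
    """
    ec_a = morgan_ec(graph, ec_orders[0])
    ec_b = morgan_ec(graph, ec_orders[1])
    pt2 = path_counts(graph, 2)
    pt3 = path_counts(graph, 3)
    s2 = valence_shells(graph, 2)
    s3 = valence_shells(graph, 3)
    counts: Counter[AttributeKey] = Counter()
    for v in range(graph.n_vertices):
        el = graph.elements[v]
        for ns, tag, a, b in (
            (EC, "ec", ec_a[v], ec_b[v]),
            (PT, "pt", pt2[v], pt3[v]),
            (SHELL, "s", s2[v], s3[v]),
        ):
            counts[AttributeKey(ns, f"{el}|{tag}a={a}")] += 1
            counts[AttributeKey(ns, f"{el}|{tag}b={b}")] += 1
            counts[AttributeKey(COMBO, f"{el}|{tag}sum={a + b}")] += 1
            counts[AttributeKey(COMBO, f"{el}|{tag}dif={abs(a - b)}")] += 1
    counts.update(ring_codes(graph))
    return counts
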