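"""Dependency-graph data model and shortest-dependency-path (SDP) extraction.

The syntactic structure of a sentence is a set of labeled, directed
head→dependent edges over token indices.  The SDP between two target
entities is the minimal-edge path connecting them in the *undirected* view
of that edge set; the original direction of each traversed edge is kept as
a per-step ``up`` (toward the head) / ``down`` (away from it) annotation.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DependencyGraph:
    """Labeled dependency edges over the tokens of one sentence.

    Parameters
    ----------
    n_tokens:
        Number of tokens in the sentence.
    edges:
        Frozen set of ``(head, dependent, relation)`` triples with 0-based
        token indices.  The root is a token with no incoming edge.
    root:
        Index of the root token.
    """

    n_tokens: int
    edges: frozenset[tuple[int, int, str]]
    root: int

    def __post_init__(self) -> None:
        for h, d, _rel in self.edges:
            if h == d:
                raise ValueError(f"self-loop on token {h}")
            if not (0 <= h < self.n_tokens and 0 <= d < self.n_tokens):
                raise ValueError(f"edge ({h},{d}) outside [0,{self.n_tokens})")
        if not 0 <= self.root < self.n_tokens:
            raise ValueError(f"root {self.root} outside [0,{self.n_tokens})")
        dependents = [d for _h, d, _r in self.edges]
        if len(dependents) != len(set(dependents)):
            logger.warning("dependency graph is not a tree: token with multiple heads")

    def adjacency(self) -> list[list[tuple[int, str, str]]]:
        """Undirected adjacency: for each token, ``(neighbor, relation, direction)``.

        ``direction`` is the direction of travel *from* the token *to* the
        neighbor: ``up`` when the neighbor is the head of the original edge.
        Neighbor lists are sorted for deterministic traversal.
        """
        adj: list[list[tuple[int, str, str]]] = [[] for _ in range(self.n_tokens)]
        for h, d, rel in sorted(self.edges):
            adj[d].append((h, rel, UP))
            adj[h].append((d, rel, DOWN))
        for lst in adj:
            lst.sort()
        return adj

    def is_tree(self) -> bool:
        if len(self.edges) != self.n_tokens - 1:
            return False
        seen = {self.root}
        queue = deque([self.root])
        children: dict[int, list[int]] = {}
        for h, d, _ in self.edges:
            children.setdefault(h, []).append(d)
        while queue:
            u = queue.popleft()
            for v in children.get(u, []):
                if v in seen:
                    return False
                seen.add(v)
                queue.append(v)
        return len(seen) == self.n_tokens


@dataclass(frozen=True)
class SDPath:
    """An SDP: token indices p1..pm, per-step relation labels d1..d(m-1),
    and per-step traversal directions."""

    nodes: tuple[int, ...]
    relations: tuple[str, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.relations) != len(self.nodes) - 1:
            raise ValueError("need exactly one relation per step")
        if len(self.directions) != len(self.relations):
            raise ValueError("need exactly one direction per step")
        if any(d not in (UP, DOWN) for d in self.directions):
            raise ValueError("directions must be 'up' or 'down'")

    def __len__(self) -> int:
        return len(self.nodes)

    def arrow_notation(self, tokens: list[str] | None = None) -> str:
        """Render the path as ``word –rel→ word`` for logs and debugging."""
        name = (lambda i: tokens[i]) if tokens is not None else str
        out = [name(self.nodes[0])]
        for rel, node in zip(self.relations, self.nodes[1:]):
            out.append(f"–{rel}→ {name(node)}")
        return " ".join(out)


def path_reverse(path: SDPath) -> SDPath:
    """Reverse a path: the SDP from b to a, given the SDP from a to b."""
    flip = {UP: DOWN, DOWN: UP}
    return SDPath(
        nodes=path.nodes[::-1],
        relations=path.relations[::-1],
        directions=tuple(flip[d] for d in path.directions[::-1]),
    )


def shortest_dependency_path(graph: DependencyGraph, a: int, b: int) -> SDPath | None:
    """Breadth-first shortest path from token ``a`` to token ``b``.

    The search runs on the undirected view of the edge set.  Among
    equal-length paths (possible only in non-tree graphs) the
    lexicographically smallest node sequence is returned, which makes the
    result reproducible.  Returns ``None`` when the two tokens are not
    connected; callers fall back to sentence-only features.
    """
    if a == b:
        raise ValueError("the two target tokens must differ")
    for idx in (a, b):
        if not 0 <= idx < graph.n_tokens:
            raise ValueError(f"token index {idx} outside [0,{graph.n_tokens})")

    adj = graph.adjacency()
    dist_a = _bfs_distances(adj, a)
    if dist_a[b] < 0:
        return None
    dist_b = _bfs_distances(adj, b)
    total = dist_a[b]

    # Greedy construction: from each node pick the smallest-index neighbor
    # that still lies on some shortest a→b path.  This yields the
    # lexicographically smallest node sequence.
    nodes = [a]
    relations: list[str] = []
    directions: list[str] = []
    current = a
    while current != b:
        step = None
        for v, rel, direction in adj[current]:
            if dist_a[v] == dist_a[current] + 1 and dist_a[v] + dist_b[v] == total:
                step = (v, rel, direction)
                break  # adjacency is sorted, first hit is smallest
        assert step is not None, "BFS invariant violated"
        current = step[0]
        nodes.append(current)
        relations.append(step[1])
        directions.append(step[2])
    return SDPath(tuple(nodes), tuple(relations), tuple(directions))


def _bfs_distances(adj: list[list[tuple[int, str, str]]], source: int) -> list[int]:
    dist = [-1] * len(adj)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v, _rel, _dir in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist
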