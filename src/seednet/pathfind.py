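"""Bounded graph-search primitives over an interaction universe.

All algorithms share the traversal rule defined by :mod:`seednet.universe`
(directed edges one way, undirected and complex-membership edges both ways),
return only simple paths, and break every tie lexicographically on node
identifiers, so results are deterministic without a seed.  ``maxlen`` always
counts *edges*, not nodes.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .universe import Universe

__all__ = [
    "Path",
    "CascadeResult",
    "CoverResult",
    "shortest_paths",
    "dfs_path",
    "all_paths",
    "upstream_cascades",
    "minimal_regulator_cover",
]


@dataclass(frozen=True)
class Path:
    """A simple path: consecutive node pairs are traversable universe edges."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes, self.nodes[1:]))

    def __iter__(self):
        return iter(self.nodes)


@dataclass
class CascadeResult:
    """Layered upstream regulators of a target set.

    ``layers[k-1]`` maps each depth-``k`` regulator to the set of nodes from
    the previous layer (the targets themselves for ``k=1``) that it directly
    regulates.  ``rankings[k-1]`` orders that layer's regulators by coverage
    count (descending, ties broken by identifier).
    """

    layers: list[dict[str, frozenset[str]]]
    rankings: list[list[tuple[str, int]]]

    @property
    def ranking(self) -> list[tuple[str, int]]:
        """Aggregate ranking across layers (total coverage, ties by name)."""
        totals: dict[str, int] = {}
        for layer in self.layers:
            for reg, covered in layer.items():
                totals[reg] = totals.get(reg, 0) + len(covered)
        return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


class CoverResult(NamedTuple):
    cover: set[str]
    uncovered: set[str]
    ranking: list[tuple[str, int]]
    exact: bool


def _succ(universe: Universe, node: str, signed_only: bool, directed_only: bool):
    return sorted(
        universe.successors(node, signed_only=signed_only, directed_only=directed_only)
    )


def shortest_paths(
    universe: Universe,
    source: str,
    target: str,
    maxlen: int,
    signed_only: bool = False,
    directed_only: bool = False,
) -> list[Path]:
    """All simple paths of the minimal length L <= maxlen, sorted.

    Returns an empty list when no path of length <= ``maxlen`` exists or an
    endpoint is unknown; ``source == target`` yields the single length-0 path.
    """
    if maxlen < 1:
        raise ValueError("maxlen must be >= 1")
    nodes = universe.node_set
    if source not in nodes or target not in nodes:
        return []
    if source == target:
        return [Path((source,))]
    # BFS distance labelling from the source, capped at maxlen
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] >= maxlen:
            continue
        for v in _succ(universe, u, signed_only, directed_only):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if target not in dist:
        return []
    # enumerate all paths along strictly distance-increasing edges
    goal = dist[target]
    results: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        u = path[-1]
        if u == target:
            results.append(tuple(path))
            return
        for v in _succ(universe, u, signed_only, directed_only):
            if dist.get(v) == dist[u] + 1 and dist[v] <= goal:
                path.append(v)
                extend(path)
                path.pop()

    extend([source])
    return [Path(p) for p in sorted(results)]


def dfs_path(
    universe: Universe,
    source: str,
    target: str,
    maxlen: int,
    signed_only: bool = False,
    directed_only: bool = False,
) -> Path | None:
    """First simple path found by depth-first search, or None.

    Neighbors are explored in lexicographic order, so the result is
    deterministic but not necessarily shortest.
    """
    if maxlen < 1:
        raise ValueError("maxlen must be >= 1")
    nodes = universe.node_set
    if source not in nodes or target not in nodes:
        return None
    if source == target:
        return Path((source,))

    path = [source]
    on_path = {source}

    def search() -> bool:
        u = path[-1]
        if len(path) - 1 >= maxlen:
            return False
        for v in _succ(universe, u, signed_only, directed_only):
            if v in on_path:
                continue
            path.append(v)
            if v == target:
                return True
            on_path.add(v)
            if search():
                return True
            on_path.discard(v)
            path.pop()
        return False

    return Path(tuple(path)) if search() else None


def all_paths(
    universe: Universe,
    source: str,
    target: str,
    maxlen: int,
    signed_only: bool = False,
    directed_only: bool = False,
) -> list[Path]:
    """All simple paths of length <= maxlen, sorted lexicographically."""
    if maxlen < 1:
        raise ValueError("maxlen must be >= 1")
    nodes = universe.node_set
    if source not in nodes or target not in nodes:
        return []
    if source == target:
        return [Path((source,))]
    results: list[tuple[str, ...]] = []
    path = [source]
    on_path = {source}

    def search() -> None:
        u = path[-1]
        if len(path) - 1 >= maxlen:
            return
        for v in _succ(universe, u, signed_only, directed_only):
            if v in on_path:
                continue
            path.append(v)
            if v == target:
                results.append(tuple(path))
            else:
                on_path.add(v)
                search()
                on_path.discard(v)
            path.pop()

    search()
    return [Path(p) for p in sorted(results)]


def _regulators(universe: Universe, node: str) -> set[str]:
    """Direct regulators: traversable upstream neighbors, excluding the node."""
    return universe.predecessors(node) - {node}


def upstream_cascades(
    universe: Universe, targets: Iterable[str], depth: int = 1
) -> CascadeResult:
    """Layered upstream regulator discovery.

    Layer 1 maps each direct regulator of any target to the targets it
    regulates; layer k maps regulators of the layer-(k-1) regulators.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    layers: list[dict[str, frozenset[str]]] = []
    rankings: list[list[tuple[str, int]]] = []
    current = sorted(targets)
    for _ in range(depth):
        layer: dict[str, set[str]] = {}
        for t in current:
            for reg in _regulators(universe, t):
                layer.setdefault(reg, set()).add(t)
        frozen = {reg: frozenset(members) for reg, members in layer.items()}
        layers.append(frozen)
        rankings.append(
            sorted(
                ((reg, len(members)) for reg, members in frozen.items()),
                key=lambda kv: (-kv[1], kv[0]),
            )
        )
        if not frozen:
            current = []
        else:
            current = sorted(frozen)
    return CascadeResult(layers=layers, rankings=rankings)


def _min_cover(
    coverage: dict[str, frozenset[str]],
    targets: set[str],
    exact_threshold: int,
) -> tuple[set[str], bool]:
    """Smallest candidate subset covering ``targets``.

    Exact (ascending-size combination scan, lexicographic within a size) when
    the candidate count is at most ``exact_threshold``; greedy
    largest-coverage-first with lexicographic tie-break otherwise.
    """
    candidates = sorted(coverage)
    if not targets:
        return set(), True
    if len(candidates) <= exact_threshold:
        for size in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                covered = set().union(*(coverage[c] for c in combo))
                if targets <= covered:
                    return set(combo), True
        return set(candidates), True  # unreachable when targets are coverable
    chosen: set[str] = set()
    remaining = set(targets)
    while remaining:
        best = min(candidates, key=lambda c: (-len(coverage[c] & remaining), c))
        gain = coverage[best] & remaining
        if not gain:
            break
        chosen.add(best)
        remaining -= gain
    return chosen, False


def minimal_regulator_cover(
    universe: Universe,
    targets: Iterable[str],
    exact_threshold: int = 15,
) -> CoverResult:
    """A smallest set of direct regulators covering every coverable target.

    Targets with no regulators at all are reported in ``uncovered`` rather
    than silently dropped.  The search is exact (brute force over candidate
    subsets) when there are at most ``exact_threshold`` candidate regulators
    and greedy otherwise; ``CoverResult.exact`` reports which mode ran.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    coverage: dict[str, set[str]] = {}
    for t in sorted(targets):
        for reg in _regulators(universe, t):
            coverage.setdefault(reg, set()).add(t)
    frozen = {reg: frozenset(members) for reg, members in coverage.items()}
    coverable = set().union(*frozen.values()) if frozen else set()
    uncovered = targets - coverable
    cover, exact = _min_cover(frozen, coverable, exact_threshold)
    ranking = sorted(
        ((reg, len(members)) for reg, members in frozen.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return CoverResult(cover=cover, uncovered=uncovered, ranking=ranking, exact=exact)
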