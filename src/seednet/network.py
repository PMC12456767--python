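"""The working network model and the five seed-connection strategies.

A :class:`Network` starts from user seeds (or a SIF file) and grows by
drawing paths and edges from a :class:`~seednet.universe.Universe`:

* **RPE** (reciprocal pathway extension) — for every ordered seed pair with
  no existing path, add all minimal-length universe paths (BFS) or one DFS
  path, then wire each newly added node to the pre-existing network.
* **INE** (iterative neighbor expansion) — breadth-wise neighborhood growth
  with edge induction, stopping once the seeds share a weakly connected
  component, followed by pruning.
* **RCE** (regulatory cascade exploration) — layered upstream-regulator
  ranking of designated output nodes, optionally attaching a minimal
  regulator cover per layer.
* **MCM** (module connection mapping) — bounded path enumeration between two
  node groups (IN / OUT / ALL modes), with the intermediates (Group C)
  interconnected by RPE.
* **PINC** lives in :mod:`seednet.ontology` and reuses MCM plus
  :meth:`Network.merge_nodes`.

Strategies mutate the network in place, return it (or their result object)
and append exactly one provenance record per invocation.  All iteration
orders are sorted, so identical inputs always produce identical networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from . import pathfind
from .universe import Effect, Interaction, Universe

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Edge",
    "NodeGroup",
    "CompositeNode",
    "Network",
    "init_network",
    "load_sif_network",
    "modify_network",
    "connect_rpe",
    "connect_ine",
    "connect_rce",
    "connect_mcm",
    "expand_complexes",
    "prune",
]


@dataclass
class Node:
    symbol: str
    accession: str | None = None
    is_seed: bool = False


@dataclass
class Edge:
    source: str
    target: str
    effect: Effect
    edge_type: str = "database"
    references: tuple[str, ...] = ()
    directed: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.effect.value)


@dataclass(frozen=True)
class NodeGroup:
    """A named set of entities used by the module-connection strategy."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"node group {self.name!r} has no members")


@dataclass
class CompositeNode:
    """A phenotype node that replaced a set of merged member genes."""

    name: str
    members: frozenset[str]
    inherited_edges: tuple[tuple[str, str, str], ...]


class Network:
    """Seeded working network backed by a prior-knowledge universe."""

    def __init__(self, seeds: Iterable[str], universe: Universe):
        seeds = [s.strip() for s in seeds if s and s.strip()]
        if not seeds:
            raise ValueError("at least one seed is required")
        self.nodes: dict[str, Node] = {}
        self.edges: dict[tuple[str, str, str], Edge] = {}
        self.provenance_log: list[dict] = []
        self.composites: dict[str, CompositeNode] = {}
        present = universe.node_set
        missing = sorted(set(seeds) - present)
        for m in missing:
            logger.warning("seed %s not found in universe; ignored", m)
        kept = sorted(set(seeds) & present)
        if not kept:
            raise ValueError("no seeds found in universe")
        for s in kept:
            self.nodes[s] = Node(symbol=s, is_seed=True)
        # induce universe edges among the seeds
        for u in kept:
            for v in kept:
                for it in universe.edges_between(u, v):
                    self._add_interaction(it)
        self._log("init", {"seeds": kept, "missing_seeds": missing})

    # -- construction alternatives -----------------------------------------

    @classmethod
    def from_sif(cls, path, universe: Universe) -> "Network":
        """Load an existing SIF network to be expanded.

        All file nodes are flagged as seeds; edges absent from the universe
        are retained with edge_type ``user``.
        """
        from .exports import read_sif

        edges, isolated = read_sif(path)
        net = cls.__new__(cls)
        net.nodes = {}
        net.edges = {}
        net.provenance_log = []
        net.composites = {}
        if not edges and not isolated:
            raise ValueError(f"empty SIF file: {path}")
        for name in isolated:
            net.nodes.setdefault(name, Node(symbol=name, is_seed=True))
        for source, effect, target in edges:
            net.nodes.setdefault(source, Node(symbol=source, is_seed=True))
            net.nodes.setdefault(target, Node(symbol=target, is_seed=True))
            known = any(
                it.effect is effect
                for it in universe.edges_between(source, target)
            )
            net._add_edge(
                Edge(
                    source=source,
                    target=target,
                    effect=effect,
                    edge_type="database" if known else "user",
                    directed=effect is not Effect.FORM_COMPLEX,
                )
            )
        net._log("load_sif", {"path": str(path)})
        return net

    # -- bookkeeping ---------------------------------------------------------

    def _log(self, strategy: str, params: dict) -> None:
        self.provenance_log.append({"strategy": strategy, "params": params})

    @property
    def seed_nodes(self) -> list[str]:
        return sorted(n.symbol for n in self.nodes.values() if n.is_seed)

    def sorted_edges(self) -> list[Edge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def isolated_nodes(self) -> list[str]:
        linked = set()
        for e in self.edges.values():
            linked.add(e.source)
            linked.add(e.target)
        return sorted(set(self.nodes) - linked)

    def _add_node(self, symbol: str, is_seed: bool = False) -> None:
        if symbol not in self.nodes:
            self.nodes[symbol] = Node(symbol=symbol, is_seed=is_seed)

    def _add_edge(self, edge: Edge) -> None:
        self._add_node(edge.source)
        self._add_node(edge.target)
        existing = self.edges.get(edge.key)
        if existing is None:
            self.edges[edge.key] = edge
        else:
            existing.references = tuple(
                sorted(set(existing.references) | set(edge.references))
            )
            existing.directed = existing.directed or edge.directed

    def _add_interaction(self, it: Interaction, edge_type: str = "database") -> None:
        self._add_edge(
            Edge(
                source=it.source,
                target=it.target,
                effect=it.effect,
                edge_type=edge_type,
                references=it.references,
                directed=it.traversal_directed,
            )
        )

    def _add_pair_edges(self, universe: Universe, u: str, v: str, **filters) -> int:
        """Add every universe interaction traversable u -> v; return count."""
        added = 0
        for it in universe.edges_between(u, v, **filters):
            self._add_interaction(it)
            added += 1
        return added

    def _add_path(self, universe: Universe, path: pathfind.Path, **filters) -> None:
        for u, v in path.edges():
            self._add_pair_edges(universe, u, v, **filters)

    # -- traversal inside the network ---------------------------------------

    def _successors(self, node: str) -> set[str]:
        out = set()
        for e in self.edges.values():
            if e.source == node and (e.directed or True):
                out.add(e.target)
            elif not e.directed and e.target == node:
                out.add(e.source)
        return out

    def has_path(self, source: str, target: str, maxlen: int | None = None) -> bool:
        """Directed reachability within the current network (BFS)."""
        if source not in self.nodes or target not in self.nodes:
            return False
        if source == target:
            return True
        # forward adjacency honouring per-edge directedness
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges.values():
            adj[e.source].add(e.target)
            if not e.directed:
                adj[e.target].add(e.source)
        frontier = {source}
        seen = {source}
        depth = 0
        while frontier:
            if maxlen is not None and depth >= maxlen:
                return False
            depth += 1
            frontier = set().union(*(adj[u] for u in frontier)) - seen
            if target in frontier:
                return True
            seen |= frontier
        return False

    def in_degree(self, node: str) -> int:
        deg = 0
        for e in self.edges.values():
            if e.target == node or (not e.directed and e.source == node):
                deg += 1
        return deg

    def _undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges.values())
        return g

    # -- editing -------------------------------------------------------------

    def add_node(self, symbol: str) -> None:
        self._add_node(symbol)
        self._log("add_node", {"node": symbol})

    def remove_node(self, symbol: str) -> None:
        if symbol not in self.nodes:
            logger.warning("remove_node: %s not in network; no-op", symbol)
            return
        self._remove_node_silent(symbol)
        self._log("remove_node", {"node": symbol})

    def _remove_node_silent(self, symbol: str) -> None:
        del self.nodes[symbol]
        for key in [k for k, e in self.edges.items()
                    if e.source == symbol or e.target == symbol]:
            del self.edges[key]

    def add_edge_from_universe(self, universe: Universe, source: str, target: str) -> None:
        added = self._add_pair_edges(universe, source, target)
        if not added:
            raise ValueError(f"no universe interaction traversable {source} -> {target}")
        self._log("add_edge_from_universe", {"source": source, "target": target})

    def remove_edge(self, source: str, target: str) -> None:
        keys = [
            k
            for k, e in self.edges.items()
            if (e.source, e.target) == (source, target)
            or (not e.directed and (e.target, e.source) == (source, target))
        ]
        if not keys:
            logger.warning("remove_edge: %s -> %s not in network; no-op", source, target)
            return
        for k in keys:
            del self.edges[k]
        self._log("remove_edge", {"source": source, "target": target})

    def remove_path(self, nodes: Sequence[str]) -> None:
        """Remove every consecutive edge, then isolated intermediate nodes."""
        for u, v in zip(nodes, nodes[1:]):
            for k in [
                key
                for key, e in self.edges.items()
                if (e.source, e.target) == (u, v)
                or (not e.directed and (e.target, e.source) == (u, v))
            ]:
                del self.edges[k]
        for inner in nodes[1:-1]:
            if inner in self.nodes and self.in_degree(inner) == 0 and not self._successors(inner):
                if not any(
                    e.source == inner or e.target == inner for e in self.edges.values()
                ):
                    del self.nodes[inner]
        self._log("remove_path", {"path": list(nodes)})

    # -- strategies ----------------------------------------------------------

    def _integrate_new_nodes(
        self, universe: Universe, new_nodes: Iterable[str], prior: Iterable[str], **filters
    ) -> list[tuple[str, str]]:
        """Add direct universe edges between new nodes and pre-existing ones."""
        added = []
        for n in sorted(new_nodes):
            for m in sorted(prior):
                if n == m:
                    continue
                if self._add_pair_edges(universe, n, m, **filters):
                    added.append((n, m))
                if self._add_pair_edges(universe, m, n, **filters):
                    added.append((m, n))
        return added

    def _rpe_over(
        self,
        universe: Universe,
        members: list[str],
        maxlen: int,
        algorithm: str,
        signed_only: bool,
        escalate_maxlen: int | None,
        record: dict,
    ) -> None:
        """Core RPE loop over ordered pairs of ``members``."""
        filters = {"signed_only": signed_only}
        for s in members:
            for t in members:
                if s == t:
                    continue
                if self.has_path(s, t, maxlen):
                    continue
                paths = self._find_paths(universe, s, t, maxlen, algorithm, signed_only)
                if not paths and escalate_maxlen and escalate_maxlen > maxlen:
                    paths = self._find_paths(
                        universe, s, t, escalate_maxlen, algorithm, signed_only
                    )
                if not paths:
                    record["unconnected_pairs"].append((s, t))
                    logger.info("RPE: no universe path %s -> %s within bound", s, t)
                    continue
                prior = set(self.nodes)
                for p in paths:
                    self._add_path(universe, p, **filters)
                    record["path_nodes"].update(p.nodes)
                new_nodes = set(self.nodes) - prior
                record["added_nodes"].update(new_nodes)
                self._integrate_new_nodes(universe, new_nodes, prior, **filters)

    @staticmethod
    def _find_paths(universe, s, t, maxlen, algorithm, signed_only):
        if algorithm == "bfs":
            return pathfind.shortest_paths(universe, s, t, maxlen, signed_only=signed_only)
        if algorithm == "dfs":
            p = pathfind.dfs_path(universe, s, t, maxlen, signed_only=signed_only)
            return [p] if p else []
        raise ValueError(f"unknown algorithm {algorithm!r} (expected 'bfs' or 'dfs')")

    def connect_rpe(
        self,
        universe: Universe,
        maxlen: int = 3,
        algorithm: str = "bfs",
        signed_only: bool = False,
        escalate_maxlen: int | None = None,
    ) -> "Network":
        """Connect every ordered seed pair, adding intermediate nodes.

        Pairs already connected inside the current network are skipped; for
        the rest all minimal-length universe paths (``bfs``) or a single
        deterministic DFS path (``dfs``) of length <= ``maxlen`` are added,
        and each newly added node is wired to the pre-existing network by its
        direct universe edges before the next pair is processed.
        """
        seeds = self.seed_nodes
        if len(seeds) < 2:
            raise ValueError("RPE requires at least two seed nodes")
        record = {
            "unconnected_pairs": [],
            "added_nodes": set(),
            "path_nodes": set(),
        }
        self._rpe_over(universe, seeds, maxlen, algorithm, signed_only, escalate_maxlen, record)
        self._log(
            "rpe",
            {
                "maxlen": maxlen,
                "algorithm": algorithm,
                "signed_only": signed_only,
                "escalate_maxlen": escalate_maxlen,
                "unconnected_pairs": sorted(record["unconnected_pairs"]),
                "added_nodes": sorted(record["added_nodes"]),
                "path_nodes": sorted(record["path_nodes"]),
            },
        )
        return self

    def _induce_edges(self, universe: Universe, **filters) -> None:
        """Add all universe edges among the current node set."""
        current = sorted(self.nodes)
        members = set(current)
        for u in current:
            for v in universe.successors(u, **filters):
                if v in members:
                    self._add_pair_edges(universe, u, v, **filters)

    def _seeds_connected(self) -> bool:
        seeds = set(self.seed_nodes)
        if len(seeds) < 2:
            return True
        g = self._undirected_graph()
        comp = nx.node_connected_component(g, next(iter(sorted(seeds))))
        return seeds <= comp

    def connect_ine(
        self,
        universe: Universe,
        max_iterations: int = 2,
        signed_only: bool = False,
    ) -> "Network":
        """Iterative neighbor expansion with edge induction and final pruning.

        Iteration k adds all universe neighbors (both directions) of the
        nodes added at iteration k-1 (the seeds for k=1), then induces all
        universe edges among current nodes.  Expansion stops early once every
        seed lies in one weakly connected component; the network is then
        pruned of disconnected and non-regulated nodes (seeds protected).
        """
        if max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        filters = {"signed_only": signed_only}
        self._induce_edges(universe, **filters)
        frontier = sorted(self.nodes)
        iterations_run = 0
        connected = self._seeds_connected()
        while not connected and iterations_run < max_iterations:
            iterations_run += 1
            new_nodes: set[str] = set()
            for u in frontier:
                new_nodes |= universe.successors(u, **filters)
                new_nodes |= universe.predecessors(u, **filters)
            new_nodes -= set(self.nodes)
            for n in sorted(new_nodes):
                self._add_node(n)
            self._induce_edges(universe, **filters)
            connected = self._seeds_connected()
            frontier = sorted(new_nodes)
            if not new_nodes:
                break
        if not connected:
            logger.warning(
                "INE: seeds still disconnected after %d iteration(s)", iterations_run
            )
        self._prune_silent(protect_seeds=True)
        self._log(
            "ine",
            {
                "max_iterations": max_iterations,
                "signed_only": signed_only,
                "iterations_run": iterations_run,
                "seeds_connected": connected,
            },
        )
        return self

    def connect_rce(
        self,
        universe: Universe,
        outputs: Iterable[str],
        depth: int = 1,
        attach: bool = False,
    ) -> pathfind.CascadeResult:
        """Rank upstream regulators of output nodes; optionally attach covers.

        Returns the layered cascade; with ``attach=True`` the minimal
        regulator cover of each layer (and its regulator→regulated edges) is
        added to the network.
        """
        outputs = set(outputs)
        offenders = sorted(outputs - set(self.nodes))
        if offenders:
            raise ValueError(f"outputs not in network: {offenders}")
        cascade = pathfind.upstream_cascades(universe, outputs, depth=depth)
        attached: list[str] = []
        if attach:
            for layer in cascade.layers:
                regulated = set().union(*layer.values()) if layer else set()
                cover, _ = pathfind._min_cover(layer, regulated, exact_threshold=15)
                for reg in sorted(cover):
                    self._add_node(reg)
                    attached.append(reg)
                    for tgt in sorted(layer[reg]):
                        self._add_pair_edges(universe, reg, tgt)
        self._log(
            "rce",
            {
                "outputs": sorted(outputs),
                "depth": depth,
                "attach": attach,
                "attached": attached,
                "ranking": cascade.ranking,
            },
        )
        return cascade

    def connect_mcm(
        self,
        universe: Universe,
        group_a: NodeGroup | Iterable[str],
        group_b: NodeGroup | Iterable[str],
        mode: str = "OUT",
        maxlen: int = 2,
    ) -> "Network":
        """Connect two node groups via bounded simple-path enumeration.

        OUT searches a→b, IN searches b→a (both restricted to directed
        interactions), ALL searches both orientations under the normal
        traversal rule.  Intermediate nodes of found paths form Group C,
        which is then interconnected with the RPE procedure.
        """
        ga = group_a if isinstance(group_a, NodeGroup) else NodeGroup("A", frozenset(group_a))
        gb = group_b if isinstance(group_b, NodeGroup) else NodeGroup("B", frozenset(group_b))
        if ga.members & gb.members:
            raise ValueError(
                f"groups overlap: {sorted(ga.members & gb.members)}"
            )
        mode = mode.upper()
        if mode not in ("IN", "OUT", "ALL"):
            raise ValueError(f"mode must be IN, OUT or ALL, got {mode!r}")
        present = universe.node_set
        members_a = sorted(ga.members & present)
        members_b = sorted(gb.members & present)
        for absent in sorted((ga.members | gb.members) - present):
            logger.warning("MCM: %s absent from universe; dropped", absent)
        if not members_a or not members_b:
            raise ValueError("a node group is entirely absent from the universe")
        directed_only = mode in ("IN", "OUT")
        pairs: list[tuple[str, str]] = []
        if mode in ("OUT", "ALL"):
            pairs += [(a, b) for a in members_a for b in members_b]
        if mode in ("IN", "ALL"):
            pairs += [(b, a) for a in members_a for b in members_b]
        filters = {"directed_only": directed_only}
        group_c: set[str] = set()
        path_edges: set[tuple[str, str]] = set()
        endpoints = set(members_a) | set(members_b)
        for s, t in sorted(pairs):
            for p in pathfind.all_paths(universe, s, t, maxlen, directed_only=directed_only):
                self._add_path(universe, p, **filters)
                path_edges.update(p.edges())
                group_c.update(set(p.nodes) - endpoints)
        record = {"unconnected_pairs": [], "added_nodes": set(), "path_nodes": set()}
        if len(group_c) >= 2:
            self._rpe_over(
                universe, sorted(group_c), maxlen, "bfs", False, None, record
            )
        self._log(
            "mcm",
            {
                "group_a": members_a,
                "group_b": members_b,
                "mode": mode,
                "maxlen": maxlen,
                "group_c": sorted(group_c),
                "path_edges": sorted(path_edges),
            },
        )
        return self

    def expand_complexes(self, universe: Universe) -> "Network":
        """Pull in all components of complex nodes present in the network.

        For every node that is the target of ``form_complex`` universe
        records, the component nodes and their membership edges are added;
        each component also gains its direct universe edges to nodes that
        were already in the network.
        """
        prior = sorted(self.nodes)
        added_components: set[str] = set()
        for name in prior:
            membership = [
                it
                for it in universe.interactions
                if it.form_complex and it.target == name
            ]
            for it in sorted(membership, key=lambda i: i.source):
                if it.source not in self.nodes:
                    added_components.add(it.source)
                self._add_interaction(it)
        self._integrate_new_nodes(universe, added_components, prior)
        self._log("expand_complexes", {"added_components": sorted(added_components)})
        return self

    # -- pruning -------------------------------------------------------------

    def _prune_silent(self, protect_seeds: bool = True) -> None:
        while True:
            removed = False
            if self.nodes:
                g = self._undirected_graph()
                comps = sorted(
                    nx.connected_components(g),
                    key=lambda c: (
                        -len([n for n in c if self.nodes[n].is_seed]),
                        -len(c),
                        min(c),
                    ),
                )
                keep = comps[0] if comps else set()
                for n in sorted(self.nodes):
                    if n in keep:
                        continue
                    if protect_seeds and self.nodes[n].is_seed:
                        continue
                    self._remove_node_silent(n)
                    removed = True
            indeg = {n: 0 for n in self.nodes}
            for e in self.edges.values():
                indeg[e.target] += 1
                if not e.directed:
                    indeg[e.source] += 1
            for n in sorted(self.nodes):
                if protect_seeds and self.nodes[n].is_seed:
                    continue
                if indeg[n] == 0:
                    self._remove_node_silent(n)
                    removed = True
            if not removed:
                return

    def prune(self, protect_seeds: bool = True) -> "Network":
        """Iteratively drop disconnected and non-regulated (source-less) nodes.

        Keeps the weakly connected component holding the most seeds and
        removes nodes with zero incoming edges, to a fixed point.  Seed nodes
        are exempt unless ``protect_seeds`` is false.
        """
        self._prune_silent(protect_seeds=protect_seeds)
        self._log("prune", {"protect_seeds": protect_seeds})
        return self

    # -- merging (used by the phenotype strategy) ----------------------------

    def merge_nodes(self, members: Iterable[str], name: str) -> CompositeNode:
        """Replace ``members`` by a single composite node inheriting edges.

        Each pre-merge edge (x→g) becomes (x→composite) and (g→x) becomes
        (composite→x); member–member edges are dropped (self-loops), duplicate
        inherited edges collapse, and a stimulation plus an inhibition
        inherited for the same partner and direction collapse to one bimodal
        edge.
        """
        members = set(members)
        absent = members - set(self.nodes)
        if absent:
            raise ValueError(f"cannot merge absent nodes: {sorted(absent)}")
        if name in self.nodes and name not in members:
            raise ValueError(f"composite name {name!r} collides with an existing node")
        inherited: dict[tuple[str, str, str], Edge] = {}
        for key in sorted(self.edges):
            e = self.edges[key]
            s_in = e.source in members
            t_in = e.target in members
            if not s_in and not t_in:
                continue
            if s_in and t_in:
                continue  # would become a self-loop
            new_source = name if s_in else e.source
            new_target = name if t_in else e.target
            new = Edge(
                source=new_source,
                target=new_target,
                effect=e.effect,
                edge_type=e.edge_type,
                references=e.references,
                directed=e.directed,
            )
            prev = inherited.get(new.key)
            if prev is None:
                inherited[new.key] = new
            else:
                prev.references = tuple(sorted(set(prev.references) | set(new.references)))
                prev.directed = prev.directed or new.directed
        # collapse stimulation + inhibition for the same partner/direction
        collapsed: dict[tuple[str, str, str], Edge] = {}
        pairs = {(e.source, e.target) for e in inherited.values()}
        for s, t in sorted(pairs):
            stim = inherited.get((s, t, Effect.STIMULATION.value))
            inhib = inherited.get((s, t, Effect.INHIBITION.value))
            group = [
                e
                for e in inherited.values()
                if (e.source, e.target) == (s, t)
            ]
            if stim is not None and inhib is not None:
                merged = Edge(
                    source=s,
                    target=t,
                    effect=Effect.BIMODAL,
                    edge_type=stim.edge_type,
                    references=tuple(sorted(set(stim.references) | set(inhib.references))),
                    directed=stim.directed or inhib.directed,
                )
                group = [
                    e
                    for e in group
                    if e.effect not in (Effect.STIMULATION, Effect.INHIBITION)
                ]
                group.append(merged)
            for e in group:
                prev = collapsed.get(e.key)
                if prev is None:
                    collapsed[e.key] = e
                else:
                    prev.references = tuple(sorted(set(prev.references) | set(e.references)))
        was_seed = any(self.nodes[m].is_seed for m in members)
        for m in sorted(members):
            self._remove_node_silent(m)
        self.nodes[name] = Node(symbol=name, is_seed=was_seed)
        for key in sorted(collapsed):
            self._add_edge(collapsed[key])
        composite = CompositeNode(
            name=name,
            members=frozenset(members),
            inherited_edges=tuple(sorted(collapsed)),
        )
        self.composites[name] = composite
        self._log("merge_nodes", {"name": name, "members": sorted(members)})
        return composite

    # -- summaries -----------------------------------------------------------

    def summary(self) -> dict:
        effects: dict[str, int] = {}
        for e in self.edges.values():
            effects[e.effect.value] = effects.get(e.effect.value, 0) + 1
        return {
            "nodes": len(self.nodes),
            "edges": len(self.edges),
            "seeds": len(self.seed_nodes),
            "effects": dict(sorted(effects.items())),
        }


# ---------------------------------------------------------------------------
# functional facade


def init_network(seeds: Iterable[str], universe: Universe) -> Network:
    return Network(seeds, universe)


def load_sif_network(path, universe: Universe) -> Network:
    return Network.from_sif(path, universe)


def modify_network(network: Network, action: str, payload, universe: Universe | None = None) -> Network:
    """Dispatch a single editing action onto the network."""
    if action == "add_node":
        network.add_node(payload)
    elif action == "remove_node":
        network.remove_node(payload)
    elif action == "add_edge_from_universe":
        if universe is None:
            raise ValueError("add_edge_from_universe requires the universe")
        network.add_edge_from_universe(universe, *payload)
    elif action == "remove_edge":
        network.remove_edge(*payload)
    elif action == "remove_path":
        network.remove_path(payload)
    else:
        raise ValueError(f"unknown action {action!r}")
    return network


def connect_rpe(network: Network, universe: Universe, **kwargs) -> Network:
    return network.connect_rpe(universe, **kwargs)


def connect_ine(network: Network, universe: Universe, **kwargs) -> Network:
    return network.connect_ine(universe, **kwargs)


def connect_rce(network: Network, universe: Universe, outputs, **kwargs):
    cascade = network.connect_rce(universe, outputs, **kwargs)
    return cascade, network


def connect_mcm(network: Network, universe: Universe, group_a, group_b, **kwargs) -> Network:
    return network.connect_mcm(universe, group_a, group_b, **kwargs)


def expand_complexes(network: Network, universe: Universe) -> Network:
    return network.expand_complexes(universe)


def prune(network: Network, protect_seeds: bool = True) -> Network:
    return network.prune(protect_seeds=protect_seeds)
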