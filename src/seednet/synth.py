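"""Seeded synthetic interaction universes and annotation sets.

These generators stand in for database-derived interaction resources so
every strategy and exporter can be exercised hermetically.  Edges are
sampled without replacement from the ordered node pairs of a fixed-size node
set, each edge drawing its sign class (stimulation / inhibition / bimodal /
undefined) from configurable proportions; optional complex records attach
synthetic complex nodes to sampled member genes.  A single integer seed
drives one explicit ``random.Random`` instance and all categorical draws go
through integer ranges, so output is byte-identical across runs and
platforms.  No attempt is made to mimic realistic interactome degree
distributions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .ontology import AnnotationSet
from .universe import Interaction, Universe

__all__ = ["UniverseSpec", "generate_universe", "generate_annotations"]

_WEIGHT_SCALE = 10**9


@dataclass(frozen=True)
class UniverseSpec:
    """Parameters of a synthetic interaction universe."""

    n_nodes: int = 30
    n_edges: int = 60
    p_stimulation: float = 0.45
    p_inhibition: float = 0.30
    p_bimodal: float = 0.05
    p_undefined: float = 0.20
    n_complexes: int = 0
    complex_size: tuple[int, int] = (2, 3)
    seed: int = 0

    def __post_init__(self):
        props = (
            self.p_stimulation,
            self.p_inhibition,
            self.p_bimodal,
            self.p_undefined,
        )
        if any(p < 0 for p in props):
            raise ValueError("proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(props)}")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_edges < 1:
            raise ValueError("need at least 1 edge")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"{self.n_edges} edges do not fit in "
                f"{self.n_nodes} nodes without replacement"
            )
        lo, hi = self.complex_size
        if not (2 <= lo <= hi):
            raise ValueError("complex_size must satisfy 2 <= lo <= hi")
        if self.n_complexes and hi > self.n_nodes:
            raise ValueError("complex_size exceeds the number of nodes")


def _node_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"N{i:0{width}d}" for i in range(1, n + 1)]


def _draw_class(rng: random.Random, cumulative: list[tuple[int, str]]) -> str:
    total = cumulative[-1][0]
    r = rng.randrange(total)
    for bound, label in cumulative:
        if r < bound:
            return label
    return cumulative[-1][1]


def generate_universe(spec: UniverseSpec) -> Universe:
    """Sample a signed/directed universe according to ``spec``.

    Exactly ``spec.n_edges`` distinct ordered node pairs (no self loops) are
    drawn, plus ``spec.n_complexes`` complex nodes with ``form_complex``
    membership edges.  Identical specs produce identical universes.
    """
    rng = random.Random(spec.seed)
    nodes = _node_names(spec.n_nodes)
    classes = [
        ("stimulation", spec.p_stimulation),
        ("inhibition", spec.p_inhibition),
        ("bimodal", spec.p_bimodal),
        ("undefined", spec.p_undefined),
    ]
    cumulative: list[tuple[int, str]] = []
    running = 0
    for label, p in classes:
        running += int(round(p * _WEIGHT_SCALE))
        cumulative.append((running, label))

    all_pairs = [(u, v) for u in nodes for v in nodes if u != v]
    pairs = rng.sample(all_pairs, spec.n_edges)
    interactions = []
    for u, v in sorted(pairs):
        label = _draw_class(rng, cumulative)
        interactions.append(
            Interaction(
                source=u,
                target=v,
                is_directed=True,
                is_stimulation=label in ("stimulation", "bimodal"),
                is_inhibition=label in ("inhibition", "bimodal"),
                sources=("synthetic",),
            )
        )
    for c in range(1, spec.n_complexes + 1):
        size = rng.randint(*spec.complex_size)
        members = rng.sample(nodes, size)
        complex_name = f"CPX{c:02d}"
        for m in sorted(members):
            interactions.append(
                Interaction(
                    source=m,
                    target=complex_name,
                    form_complex=True,
                    sources=("synthetic",),
                )
            )
    return Universe(interactions)


def generate_annotations(
    universe: Universe,
    n_terms: int = 3,
    genes_per_term: tuple[int, int] = (3, 6),
    seed: int = 0,
) -> AnnotationSet:
    """Sample ontology-style term→gene annotations over a universe."""
    if len(universe) == 0:
        raise ValueError("universe is empty")
    lo, hi = genes_per_term
    nodes = sorted(universe.node_set)
    if hi > len(nodes):
        raise ValueError(
            f"genes_per_term upper bound {hi} exceeds universe size {len(nodes)}"
        )
    rng = random.Random(seed)
    index: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(1, n_terms + 1):
        accession = f"GO:{i:07d}"
        size = rng.randint(lo, hi)
        members = frozenset(rng.sample(nodes, size))
        index[accession] = (f"term_{i}", members)
    return AnnotationSet(term_index=index)
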