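"""seednet: assemble signed, directed molecular networks from seed entities.

Given a tabular prior-knowledge interaction resource (the *universe*) and a
list of seed genes/proteins, seednet connects the seeds with bounded
graph-search strategies, optionally attaches ontology-derived phenotype
nodes, and exports the result as SIF, Graphviz DOT, or an ensemble of
Boolean models in BNET format.
"""

from importlib import resources as _resources

from .universe import (
    Effect,
    Interaction,
    Universe,
    UniverseFormatError,
    EmptyUniverseError,
    build_universe,
    merge_resource,
    resolve_effect,
    neighbors,
)
from .pathfind import (
    Path,
    CascadeResult,
    CoverResult,
    shortest_paths,
    dfs_path,
    all_paths,
    upstream_cascades,
    minimal_regulator_cover,
)
from .network import (
    Network,
    Node,
    Edge,
    NodeGroup,
    CompositeNode,
    init_network,
    load_sif_network,
    modify_network,
    connect_rpe,
    connect_ine,
    connect_rce,
    connect_mcm,
    expand_complexes,
    prune,
)
from .ontology import (
    AnnotationSet,
    load_annotations,
    genes_for_term,
    connect_phenotype_pinc,
)
from .exports import (
    BooleanRule,
    BooleanModelEnsemble,
    write_sif,
    read_sif,
    build_rule,
    enumerate_ensemble,
    write_bnet,
    parse_bnet,
    evaluate_step,
    write_dot,
)
from .synth import UniverseSpec, generate_universe, generate_annotations

__version__ = "0.1.0"


def toy_universe_path() -> str:
    """Path to the bundled 7-edge toy universe used in docs and tests."""
    return str(_resources.files("seednet.data") / "toy_universe.tsv")


def complex_toy_path() -> str:
    """Path to the bundled toy universe with a 2-member complex."""
    return str(_resources.files("seednet.data") / "complex_toy.tsv")
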