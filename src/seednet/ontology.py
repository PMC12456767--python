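"""Ontology-derived phenotype gene sets and the PINC strategy.

Annotation data is read from local files — either GAF 2.x (the Gene Ontology
association format) or a simple two/three-column TSV (accession, gene
[, term name]) — so that phenotype integration works fully offline.

The PINC strategy (phenotype integration and network connectivity) fetches
the genes annotated to an ontology term, connects them to the existing
network with the module-connection (MCM) strategy in ALL mode, and can then
merge the connected phenotype genes into one composite node that inherits
all their edges.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Iterable

from .network import CompositeNode, Network, NodeGroup
from .universe import Universe

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "CompositeNode",
    "load_annotations",
    "genes_for_term",
    "connect_phenotype_pinc",
]

_GO_PATTERN = re.compile(r"GO:\d{7}$")


@dataclass
class AnnotationSet:
    """Mapping ontology accession → (term name, annotated gene set)."""

    term_index: dict[str, tuple[str, frozenset[str]]]

    def accessions(self) -> list[str]:
        return sorted(self.term_index)

    def __contains__(self, accession: str) -> bool:
        return accession in self.term_index

    def __len__(self) -> int:
        return len(self.term_index)


def _check_accession(accession: str) -> None:
    if not _GO_PATTERN.match(accession):
        logger.warning(
            "accession %r does not look like a GO accession (GO: + 7 digits); "
            "accepted verbatim",
            accession,
        )


def _load_tsv(path) -> dict[str, tuple[str, set[str]]]:
    terms: dict[str, tuple[str, set[str]]] = {}
    for lineno, raw in enumerate(FsPath(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 tab-separated columns")
        accession = parts[0].strip()
        gene = parts[1].strip()
        name = parts[2].strip() if len(parts) > 2 and parts[2].strip() else accession
        if not accession or not gene:
            continue
        prev_name, genes = terms.get(accession, (name, set()))
        genes.add(gene)
        terms[accession] = (prev_name if prev_name != accession else name, genes)
    return terms


def _load_gaf(path) -> dict[str, tuple[str, set[str]]]:
    """GAF 2.x: tab-delimited, '!' comments, symbol in column 3, GO id in 5."""
    terms: dict[str, tuple[str, set[str]]] = {}
    for lineno, raw in enumerate(FsPath(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        parts = raw.split("\t")
        if len(parts) < 5:
            raise ValueError(f"line {lineno}: GAF rows need >= 5 columns")
        qualifier = parts[3].strip()
        if "NOT" in qualifier.split("|"):
            continue
        gene = parts[2].strip()
        accession = parts[4].strip()
        if not gene or not accession:
            continue
        _, genes = terms.get(accession, (accession, set()))
        genes.add(gene)
        terms[accession] = (accession, genes)
    return terms


def load_annotations(path, format: str = "tsv") -> AnnotationSet:
    """Load a term→gene annotation table from a local file.

    ``format`` is ``"tsv"`` (accession, gene[, term name]) or ``"gaf"``
    (GAF 2.x, rows with a NOT qualifier skipped).  Duplicate (term, gene)
    pairs collapse to one membership.
    """
    if format == "tsv":
        terms = _load_tsv(path)
    elif format == "gaf":
        terms = _load_gaf(path)
    else:
        raise ValueError(f"format must be 'tsv' or 'gaf', got {format!r}")
    if not terms:
        raise ValueError(f"no annotation rows parsed from {path}")
    index: dict[str, tuple[str, frozenset[str]]] = {}
    for accession in sorted(terms):
        _check_accession(accession)
        name, genes = terms[accession]
        index[accession] = (name, frozenset(genes))
    return AnnotationSet(term_index=index)


def genes_for_term(
    annotations: AnnotationSet, accession: str, universe: Universe
) -> set[str]:
    """Genes annotated to a term, restricted to entities in the universe."""
    if accession not in annotations.term_index:
        raise KeyError(
            f"unknown accession {accession!r}; available: {annotations.accessions()}"
        )
    _, genes = annotations.term_index[accession]
    present = set(genes) & universe.node_set
    if not present:
        logger.warning("no gene of term %s is present in the universe", accession)
    return present


def connect_phenotype_pinc(
    network: Network,
    universe: Universe,
    annotations: AnnotationSet,
    accession: str,
    term_name: str,
    merge: bool = True,
    maxlen: int = 2,
) -> Network:
    """Integrate an ontology term's genes and optionally merge them.

    The term's genes (those present in the universe) are connected to the
    current network with MCM in ALL mode.  With ``merge=True`` the phenotype
    genes that ended up connected in the network are replaced by a single
    composite node named ``term_name`` which inherits all their edges; if no
    phenotype gene connects, the network is returned unchanged with a
    warning.
    """
    if not network.nodes:
        raise ValueError("network is empty")
    genes = genes_for_term(annotations, accession, universe)
    if not genes:
        raise ValueError(f"term {accession} has no genes present in the universe")
    existing = set(network.nodes) - genes
    new_genes = genes - set(network.nodes)
    if existing and new_genes:
        network.connect_mcm(
            universe,
            NodeGroup("network", frozenset(existing)),
            NodeGroup(term_name, frozenset(new_genes)),
            mode="ALL",
            maxlen=maxlen,
        )
    connected = sorted(
        g
        for g in genes
        if g in network.nodes
        and any(e.source == g or e.target == g for e in network.edges.values())
    )
    if not connected:
        logger.warning(
            "PINC: no phenotype gene of %s connected; composite not created", accession
        )
        network._log(
            "pinc",
            {"accession": accession, "term_name": term_name, "merged": False},
        )
        return network
    if merge:
        network.merge_nodes(connected, term_name)
    network._log(
        "pinc",
        {
            "accession": accession,
            "term_name": term_name,
            "merged": merge,
            "connected_genes": connected,
            "maxlen": maxlen,
        },
    )
    return network
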