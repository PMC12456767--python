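"""Interaction universe: load, normalize, merge and index prior-knowledge tables.

The *universe* is the complete pool of database-derived molecular
interactions from which all connection strategies draw.  It is read from
delimited text (TSV/CSV with a header); only the ``source`` and ``target``
columns are mandatory — every other column of the canonical layout is
filled with ``False`` / empty values when absent, which yields undirected,
unsigned edges.

Traversal semantics, used consistently by every algorithm in the package:

* a *directed* interaction (``is_directed`` true, not a complex record) is
  traversable only from its source to its target;
* an *undirected* interaction is traversable in both directions;
* a ``form_complex`` record is a membership statement, not causality, and is
  treated as undirected regardless of its ``is_directed`` flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "Interaction",
    "Universe",
    "UniverseFormatError",
    "EmptyUniverseError",
    "build_universe",
    "merge_resource",
    "resolve_effect",
    "neighbors",
    "read_interaction_table",
]

#: Canonical column layout of an interaction resource.
CANONICAL_COLUMNS = (
    "source",
    "target",
    "is_directed",
    "is_stimulation",
    "is_inhibition",
    "form_complex",
    "consensus_direction",
    "consensus_stimulation",
    "consensus_inhibition",
    "references",
    "sources",
)

BOOL_COLUMNS = (
    "is_directed",
    "is_stimulation",
    "is_inhibition",
    "form_complex",
    "consensus_direction",
    "consensus_stimulation",
    "consensus_inhibition",
)

LIST_COLUMNS = ("references", "sources")


class UniverseFormatError(ValueError):
    """A resource table does not conform to the expected layout."""


class EmptyUniverseError(ValueError):
    """No valid interaction rows could be loaded."""


class Effect(str, Enum):
    """Resolved causal effect of an interaction record."""

    STIMULATION = "stimulation"
    INHIBITION = "inhibition"
    BIMODAL = "bimodal"
    FORM_COMPLEX = "form_complex"
    UNDEFINED = "undefined"

    def __str__(self) -> str:  # effect tokens appear verbatim in SIF/DOT
        return self.value


@dataclass(frozen=True)
class Interaction:
    """One prior-knowledge edge record.

    ``references`` and ``sources`` carry provenance (citation identifiers and
    resource names); they are stored as sorted tuples so records hash and
    compare deterministically.  The ``consensus_*`` flags are stored and
    re-exported but play no role in traversal or effect resolution.
    """

    source: str
    target: str
    is_directed: bool = False
    is_stimulation: bool = False
    is_inhibition: bool = False
    form_complex: bool = False
    consensus_direction: bool = False
    consensus_stimulation: bool = False
    consensus_inhibition: bool = False
    references: tuple[str, ...] = ()
    sources: tuple[str, ...] = ()

    @property
    def effect(self) -> Effect:
        return resolve_effect(self)

    @property
    def traversal_directed(self) -> bool:
        """Whether traversal must respect the source→target orientation."""
        return self.is_directed and not self.form_complex

    @property
    def dedup_key(self) -> tuple[str, str, bool, bool, bool]:
        return (
            self.source,
            self.target,
            self.is_stimulation,
            self.is_inhibition,
            self.form_complex,
        )


def resolve_effect(interaction: Interaction) -> Effect:
    """Resolve an interaction's sign flags to one of the five effects.

    Total over well-formed records: complex membership wins, then the four
    combinations of the stimulation/inhibition flags partition the rest.
    """
    if interaction.form_complex:
        return Effect.FORM_COMPLEX
    if interaction.is_stimulation and interaction.is_inhibition:
        return Effect.BIMODAL
    if interaction.is_stimulation:
        return Effect.STIMULATION
    if interaction.is_inhibition:
        return Effect.INHIBITION
    return Effect.UNDEFINED


# ---------------------------------------------------------------------------
# cell parsing helpers


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    if isinstance(value, (int,)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no", "", "nan", "none"):
        return False
    raise UniverseFormatError(f"cannot interpret {value!r} as a boolean")


def _to_list(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, float) and math.isnan(value):
        return ()
    if isinstance(value, (list, tuple, set, frozenset)):
        items = [str(v).strip() for v in value]
    else:
        items = [p.strip() for p in str(value).split(";")]
    return tuple(sorted({i for i in items if i}))


def _normalize_id(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    return str(value).strip()


# ---------------------------------------------------------------------------


class Universe:
    """Deduplicated interaction store with forward/reverse adjacency indices.

    Interactions are keyed by ``(source, target, is_stimulation,
    is_inhibition, form_complex)``; merging a record with an existing key
    unions the provenance lists and OR-s the direction/consensus flags.
    Adjacency indices are updated on every insertion so lookups never go
    stale.
    """

    def __init__(self, interactions: Iterable[Interaction] = ()):
        self._store: dict[tuple, Interaction] = {}
        # _adj[u][v] -> list of interactions traversable u -> v
        self._adj: dict[str, dict[str, list[Interaction]]] = {}
        self._radj: dict[str, dict[str, list[Interaction]]] = {}
        self.rejected: list[tuple[int, str]] = []
        for it in interactions:
            self.add_interaction(it)
        if not self._store and interactions:
            raise EmptyUniverseError("empty universe: no valid interactions")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        identifier_map: Mapping[str, str] | None = None,
    ) -> "Universe":
        uni = cls()
        uni.add_frame(frame, column_map=column_map, identifier_map=identifier_map)
        if len(uni) == 0:
            raise EmptyUniverseError("empty universe: no valid interactions")
        return uni

    @classmethod
    def from_tsv(
        cls,
        path,
        column_map: Mapping[str, str] | None = None,
        identifier_map: Mapping[str, str] | None = None,
    ) -> "Universe":
        frame = read_interaction_table(path)
        return cls.from_frame(frame, column_map=column_map, identifier_map=identifier_map)

    def add_frame(
        self,
        frame: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        identifier_map: Mapping[str, str] | None = None,
    ) -> "Universe":
        """Merge a resource table into the universe (in place).

        Missing optional columns are filled with ``False`` / empty values;
        rows with an empty source or target are rejected and reported.
        """
        if column_map:
            frame = frame.rename(columns=dict(column_map))
        frame = frame.rename(columns={c: c.strip().lower() for c in frame.columns})
        for required in ("source", "target"):
            if required not in frame.columns:
                raise UniverseFormatError(f"missing mandatory column: {required!r}")
        n_valid = 0
        for idx, row in enumerate(frame.itertuples(index=False)):
            data = dict(zip(frame.columns, row))
            source = _normalize_id(data.get("source"))
            target = _normalize_id(data.get("target"))
            if identifier_map:
                source = identifier_map.get(source, source)
                target = identifier_map.get(target, target)
            if not source or not target:
                reason = "empty source" if not source else "empty target"
                self.rejected.append((idx, reason))
                logger.warning("rejected row %d: %s", idx, reason)
                continue
            kwargs = {col: _to_bool(data.get(col)) for col in BOOL_COLUMNS}
            lists = {col: _to_list(data.get(col)) for col in LIST_COLUMNS}
            self.add_interaction(
                Interaction(source=source, target=target, **kwargs, **lists)
            )
            n_valid += 1
        if n_valid == 0 and len(self._store) == 0:
            raise EmptyUniverseError("empty universe: no valid interactions")
        return self

    def add_interaction(self, interaction: Interaction) -> None:
        if not interaction.source or not interaction.target:
            raise UniverseFormatError("interaction endpoints must be non-empty")
        key = interaction.dedup_key
        existing = self._store.get(key)
        if existing is not None:
            merged = replace(
                existing,
                is_directed=existing.is_directed or interaction.is_directed,
                consensus_direction=existing.consensus_direction
                or interaction.consensus_direction,
                consensus_stimulation=existing.consensus_stimulation
                or interaction.consensus_stimulation,
                consensus_inhibition=existing.consensus_inhibition
                or interaction.consensus_inhibition,
                references=tuple(
                    sorted(set(existing.references) | set(interaction.references))
                ),
                sources=tuple(sorted(set(existing.sources) | set(interaction.sources))),
            )
            if merged != existing:
                self._unindex(existing)
                self._store[key] = merged
                self._index(merged)
            return
        self._store[key] = interaction
        self._index(interaction)

    def merge(self, other: "Universe") -> "Universe":
        for it in other.interactions:
            self.add_interaction(it)
        return self

    # -- indexing ----------------------------------------------------------

    def _index(self, it: Interaction) -> None:
        self._adj.setdefault(it.source, {}).setdefault(it.target, []).append(it)
        self._radj.setdefault(it.target, {}).setdefault(it.source, []).append(it)
        if not it.traversal_directed:
            self._adj.setdefault(it.target, {}).setdefault(it.source, []).append(it)
            self._radj.setdefault(it.source, {}).setdefault(it.target, []).append(it)
        # endpoints must appear in the node set even when isolated one-way
        self._adj.setdefault(it.source, {})
        self._adj.setdefault(it.target, {})

    def _unindex(self, it: Interaction) -> None:
        self._adj[it.source][it.target].remove(it)
        self._radj[it.target][it.source].remove(it)
        if not it.traversal_directed:
            self._adj[it.target][it.source].remove(it)
            self._radj[it.source][it.target].remove(it)

    # -- queries -----------------------------------------------------------

    @property
    def interactions(self) -> tuple[Interaction, ...]:
        return tuple(self._store[k] for k in sorted(self._store))

    @property
    def node_set(self) -> set[str]:
        nodes: set[str] = set()
        for it in self._store.values():
            nodes.add(it.source)
            nodes.add(it.target)
        return nodes

    @property
    def succ_index(self) -> dict[str, set[str]]:
        return {
            u: {v for v, lst in targets.items() if lst}
            for u, targets in self._adj.items()
        }

    @property
    def pred_index(self) -> dict[str, set[str]]:
        return {
            v: {u for u, lst in sources.items() if lst}
            for v, sources in self._radj.items()
        }

    def __len__(self) -> int:
        return len(self._store)

    def __contains__(self, node: str) -> bool:
        return node in self.node_set

    def edges_between(
        self,
        u: str,
        v: str,
        signed_only: bool = False,
        directed_only: bool = False,
    ) -> tuple[Interaction, ...]:
        """Interactions traversable from ``u`` to ``v`` under the filters."""
        found = self._adj.get(u, {}).get(v, [])
        out = []
        for it in found:
            if signed_only and it.effect is Effect.UNDEFINED:
                continue
            if directed_only and not it.traversal_directed:
                continue
            out.append(it)
        return tuple(out)

    def successors(
        self, node: str, signed_only: bool = False, directed_only: bool = False
    ) -> set[str]:
        out = set()
        for v in self._adj.get(node, {}):
            if self.edges_between(node, v, signed_only, directed_only):
                out.add(v)
        return out

    def predecessors(
        self, node: str, signed_only: bool = False, directed_only: bool = False
    ) -> set[str]:
        out = set()
        for u in self._radj.get(node, {}):
            if self.edges_between(u, node, signed_only, directed_only):
                out.add(u)
        return out

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.interactions:
            rows.append(
                {
                    "source": it.source,
                    "target": it.target,
                    "is_directed": it.is_directed,
                    "is_stimulation": it.is_stimulation,
                    "is_inhibition": it.is_inhibition,
                    "form_complex": it.form_complex,
                    "consensus_direction": it.consensus_direction,
                    "consensus_stimulation": it.consensus_stimulation,
                    "consensus_inhibition": it.consensus_inhibition,
                    "references": ";".join(it.references),
                    "sources": ";".join(it.sources),
                }
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> pd.DataFrame:
    """Read a delimited interaction table (TSV or CSV, header required)."""
    text_path = str(path)
    sep = "," if text_path.endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


# ---------------------------------------------------------------------------
# thin functional facade matching the operation names used elsewhere


def build_universe(records, column_map: Mapping[str, str] | None = None) -> Universe:
    """Build a :class:`Universe` from a DataFrame or an iterable of row dicts."""
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if frame.empty and not list(frame.columns):
        raise EmptyUniverseError("empty universe: no rows provided")
    return Universe.from_frame(frame, column_map=column_map)


def merge_resource(universe: Universe, records) -> Universe:
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    return universe.add_frame(frame)


def neighbors(
    universe: Universe, node: str, direction: str = "out", signed_only: bool = False
) -> set[str]:
    """Neighbor lookup; unknown nodes yield an empty set."""
    if direction == "out":
        return universe.successors(node, signed_only=signed_only)
    if direction == "in":
        return universe.predecessors(node, signed_only=signed_only)
    raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")
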