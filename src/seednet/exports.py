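"""Exporters: SIF, Boolean models (BNET), DOT, and a synchronous evaluator.

Boolean rule generation follows a fixed heuristic: all activators of a node
are chained by OR, all inhibitors are chained by OR, and the two groups are
combined with AND NOT —

    node = (A1 | ... | Am) & !(I1 | ... | In)

Complex nodes instead AND their members together.  Bimodal interactions are
not given a single rule; every combination of activation/inhibition across
all bimodal edges yields one ensemble member, so an ensemble holds exactly
2^B models for B bimodal edges.  Operand order inside every OR/AND chain is
lexicographic, making all emitted text byte-stable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Iterable, Mapping

from .universe import Effect

logger = logging.getLogger(__name__)

__all__ = [
    "Expr",
    "Lit",
    "Not",
    "And",
    "Or",
    "BooleanRule",
    "BooleanModelEnsemble",
    "write_sif",
    "read_sif",
    "SifFormatError",
    "build_rule",
    "enumerate_ensemble",
    "write_bnet",
    "parse_bnet",
    "parse_bnet_text",
    "evaluate_step",
    "write_dot",
]


class SifFormatError(ValueError):
    """A SIF line could not be parsed."""


# ---------------------------------------------------------------------------
# SIF


def write_sif(network, path) -> None:
    """Write a network as tab-separated SIF, one edge per line.

    Edges are emitted in canonical (source, relation, target) order; isolated
    nodes are written as single-token lines per the SIF convention.
    """
    lines = []
    for e in network.sorted_edges():
        lines.append(f"{e.source}\t{e.effect.value}\t{e.target}")
    for n in network.isolated_nodes():
        lines.append(n)
    FsPath(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_RELATIONS = {e.value: e for e in Effect}


def read_sif(path) -> tuple[list[tuple[str, Effect, str]], list[str]]:
    """Parse a SIF file into (edge records, isolated node names)."""
    edges: list[tuple[str, Effect, str]] = []
    isolated: list[str] = []
    text = FsPath(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            isolated.append(parts[0])
            continue
        if len(parts) < 3:
            raise SifFormatError(f"line {lineno}: expected 'source relation target'")
        source, relation = parts[0], parts[1]
        if relation not in _RELATIONS:
            raise SifFormatError(
                f"line {lineno}: unknown relation {relation!r} "
                f"(expected one of {sorted(_RELATIONS)})"
            )
        for target in parts[2:]:
            edges.append((source, _RELATIONS[relation], target))
    return edges, isolated


# ---------------------------------------------------------------------------
# Boolean expression trees


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Lit(Expr):
    name: str

    def evaluate(self, state):
        return 1 if state[self.name] else 0

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, state):
        return 0 if self.operand.evaluate(state) else 1

    def to_text(self):
        inner = self.operand.to_text()
        if isinstance(self.operand, Lit):
            return f"!{inner}"
        return f"!({inner})"


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, state):
        return 1 if all(op.evaluate(state) for op in self.operands) else 0

    def to_text(self):
        parts = []
        for op in self.operands:
            text = op.to_text()
            if isinstance(op, Or):
                text = f"({text})"
            parts.append(text)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, state):
        return 1 if any(op.evaluate(state) for op in self.operands) else 0

    def to_text(self):
        return " | ".join(op.to_text() for op in self.operands)


def _or_chain(names: Iterable[str]) -> Expr:
    lits = tuple(Lit(n) for n in sorted(names))
    return lits[0] if len(lits) == 1 else Or(lits)


def _and_chain(names: Iterable[str]) -> Expr:
    lits = tuple(Lit(n) for n in sorted(names))
    return lits[0] if len(lits) == 1 else And(lits)


# ---------------------------------------------------------------------------
# rules and ensembles


@dataclass(frozen=True)
class BooleanRule:
    node: str
    activators: frozenset[str]
    inhibitors: frozenset[str]
    complex_members: frozenset[str]
    expression: Expr


@dataclass
class BooleanModelEnsemble:
    """One rule set per bimodal sign assignment (2^B members)."""

    bimodal_pairs: tuple[tuple[str, str], ...]
    assignments: list[dict[tuple[str, str], str]]
    models: list[dict[str, BooleanRule]]

    def __len__(self) -> int:
        return len(self.models)


def build_rule(
    node: str,
    incoming,
    undefined_as_activator: bool = True,
) -> BooleanRule:
    """Build the heuristic Boolean rule for one node.

    ``incoming`` are edge records targeting the node.  Complex membership
    wins: a node with ``form_complex`` edges is the AND of its members.
    Undefined-effect edges are treated as activators with a warning unless
    ``undefined_as_activator`` is false, in which case they are dropped.
    Bimodal edges must have been resolved upstream (see
    :func:`enumerate_ensemble`).
    """
    activators: set[str] = set()
    inhibitors: set[str] = set()
    members: set[str] = set()
    for e in incoming:
        if e.target != node:
            raise ValueError(f"edge {e.source}->{e.target} does not target {node}")
        if e.effect is Effect.BIMODAL:
            raise ValueError(
                f"bimodal edge {e.source}->{node} must be resolved before rule building"
            )
        if e.effect is Effect.FORM_COMPLEX:
            members.add(e.source)
        elif e.effect is Effect.STIMULATION:
            activators.add(e.source)
        elif e.effect is Effect.INHIBITION:
            inhibitors.add(e.source)
        else:  # undefined
            if undefined_as_activator:
                logger.warning(
                    "undefined edge %s -> %s treated as activator", e.source, node
                )
                activators.add(e.source)
            else:
                logger.warning("undefined edge %s -> %s dropped", e.source, node)
    if activators & inhibitors:
        raise ValueError(
            f"node {node}: regulators on both sides "
            f"{sorted(activators & inhibitors)}; resolve to bimodal first"
        )
    if members:
        expr = _and_chain(members)
    elif activators and inhibitors:
        expr = And((_or_chain(activators), Not(_or_chain(inhibitors))))
    elif activators:
        expr = _or_chain(activators)
    elif inhibitors:
        expr = Not(_or_chain(inhibitors))
    else:
        expr = Lit(node)  # input node: identity rule keeps the state defined
    return BooleanRule(
        node=node,
        activators=frozenset(activators),
        inhibitors=frozenset(inhibitors),
        complex_members=frozenset(members),
        expression=expr,
    )


def _bimodal_pairs(network) -> list[tuple[str, str]]:
    """(source, target) pairs needing per-ensemble sign resolution.

    A pair is bimodal if it carries a bimodal-effect edge, or both a
    stimulation and an inhibition edge as separate records.
    """
    by_pair: dict[tuple[str, str], set[Effect]] = {}
    for e in network.sorted_edges():
        by_pair.setdefault((e.source, e.target), set()).add(e.effect)
    pairs = []
    for pair, effects in sorted(by_pair.items()):
        if Effect.BIMODAL in effects or (
            Effect.STIMULATION in effects and Effect.INHIBITION in effects
        ):
            pairs.append(pair)
    return pairs


def enumerate_ensemble(
    network,
    cap: int = 1024,
    undefined_as_activator: bool = True,
) -> BooleanModelEnsemble:
    """Enumerate all 2^B sign assignments of the network's bimodal pairs.

    Pairs are ordered lexicographically and assignments follow binary
    counting with activation = 0, so member k of the ensemble is reproducible
    from its index alone.
    """
    pairs = _bimodal_pairs(network)
    b = len(pairs)
    if 2**b > cap:
        raise ValueError(
            f"{b} bimodal interactions would give 2^{b} models, exceeding cap={cap}"
        )
    nodes = sorted(network.nodes)
    base_edges = network.sorted_edges()
    assignments: list[dict[tuple[str, str], str]] = []
    models: list[dict[str, BooleanRule]] = []
    for idx in range(2**b):
        assignment = {
            pair: ("inhibition" if (idx >> (b - 1 - j)) & 1 else "activation")
            for j, pair in enumerate(pairs)
        }
        resolved: dict[str, dict[str, Effect]] = {n: {} for n in nodes}

        def put(target: str, source: str, effect: Effect) -> None:
            prev = resolved[target].get(source)
            if prev is None or prev is effect:
                resolved[target][source] = effect
            elif Effect.FORM_COMPLEX in (prev, effect):
                # membership wins over any causal sign
                resolved[target][source] = Effect.FORM_COMPLEX
            else:
                order = [Effect.STIMULATION, Effect.INHIBITION, Effect.UNDEFINED]
                resolved[target][source] = min(prev, effect, key=order.index)

        for e in base_edges:
            pair = (e.source, e.target)
            if pair in assignment and e.effect in (
                Effect.BIMODAL,
                Effect.STIMULATION,
                Effect.INHIBITION,
            ):
                effect = (
                    Effect.STIMULATION
                    if assignment[pair] == "activation"
                    else Effect.INHIBITION
                )
            else:
                effect = e.effect
            put(e.target, e.source, effect)

        @dataclass(frozen=True)
        class _E:
            source: str
            target: str
            effect: Effect

        model = {}
        for n in nodes:
            incoming = [
                _E(source=s, target=n, effect=eff)
                for s, eff in sorted(resolved[n].items())
            ]
            model[n] = build_rule(
                n, incoming, undefined_as_activator=undefined_as_activator
            )
        assignments.append(assignment)
        models.append(model)
    return BooleanModelEnsemble(
        bimodal_pairs=tuple(pairs), assignments=assignments, models=models
    )


# ---------------------------------------------------------------------------
# BNET writing and parsing


def _sanitize_names(names: Iterable[str]) -> dict[str, str]:
    """Map node names onto the BNET identifier alphabet [A-Za-z0-9_]."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in sorted(names):
        clean = re.sub(r"[^A-Za-z0-9_]", "_", name)
        candidate = clean
        suffix = 1
        while candidate in used:
            suffix += 1
            candidate = f"{clean}_{suffix}"
        mapping[name] = candidate
        used.add(candidate)
    return mapping


def _rename_expr(expr: Expr, mapping: Mapping[str, str]) -> Expr:
    if isinstance(expr, Lit):
        return Lit(mapping.get(expr.name, expr.name))
    if isinstance(expr, Not):
        return Not(_rename_expr(expr.operand, mapping))
    if isinstance(expr, And):
        return And(tuple(_rename_expr(op, mapping) for op in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(_rename_expr(op, mapping) for op in expr.operands))
    raise TypeError(type(expr))


def write_bnet(ensemble: BooleanModelEnsemble, directory) -> list[str]:
    """Write one ``model_<k>.bnet`` file per ensemble member.

    Node names are sanitized to the BNET alphabet; if any name changed, the
    original→sanitized mapping is written to ``name_mapping.tsv`` alongside
    the models.
    """
    if not ensemble.models:
        raise ValueError("ensemble has no models")
    outdir = FsPath(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    names = sorted(ensemble.models[0])
    mapping = _sanitize_names(names)
    paths = []
    for k, model in enumerate(ensemble.models):
        lines = ["targets, factors"]
        for node in sorted(model):
            expr = _rename_expr(model[node].expression, mapping)
            lines.append(f"{mapping[node]}, {expr.to_text()}")
        path = outdir / f"model_{k}.bnet"
        path.write_text("\n".join(lines) + "\n")
        paths.append(str(path))
    if any(mapping[n] != n for n in names):
        sidecar = outdir / "name_mapping.tsv"
        sidecar.write_text(
            "\n".join(f"{n}\t{mapping[n]}" for n in names) + "\n"
        )
    return paths


_TOKEN = re.compile(r"\s*([A-Za-z0-9_]+|[!&|()])")


def _parse_expression(text: str) -> Expr:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ValueError(f"cannot tokenize {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else None

    def take(expected=None):
        nonlocal idx
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise ValueError(f"unexpected token {tok!r} in {text!r}")
        idx += 1
        return tok

    def factor() -> Expr:
        tok = peek()
        if tok == "!":
            take()
            return Not(factor())
        if tok == "(":
            take()
            inner = expression()
            take(")")
            return inner
        name = take()
        if not re.fullmatch(r"[A-Za-z0-9_]+", name):
            raise ValueError(f"bad identifier {name!r}")
        return Lit(name)

    def term() -> Expr:
        ops = [factor()]
        while peek() == "&":
            take()
            ops.append(factor())
        return ops[0] if len(ops) == 1 else And(tuple(ops))

    def expression() -> Expr:
        ops = [term()]
        while peek() == "|":
            take()
            ops.append(term())
        return ops[0] if len(ops) == 1 else Or(tuple(ops))

    result = expression()
    if peek() is not None:
        raise ValueError(f"trailing tokens in {text!r}")
    return result


def parse_bnet_text(text: str) -> dict[str, Expr]:
    """Parse BNET text (``targets, factors`` dialect) into expression trees."""
    rules: dict[str, Expr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'target, factors'")
        name, _, body = line.partition(",")
        rules[name.strip()] = _parse_expression(body.strip())
    return rules


def parse_bnet(path) -> dict[str, Expr]:
    return parse_bnet_text(FsPath(path).read_text())


def evaluate_step(model, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update of a rule set.

    ``model`` maps node → :class:`BooleanRule` or node → :class:`Expr`.
    Every model node must be assigned in ``state``.
    """
    missing = sorted(set(model) - set(state))
    if missing:
        raise ValueError(f"state missing nodes: {missing}")
    nxt = {}
    for node, rule in model.items():
        expr = rule.expression if isinstance(rule, BooleanRule) else rule
        nxt[node] = expr.evaluate(state)
    return nxt


# ---------------------------------------------------------------------------
# DOT


_ARROWHEADS = {
    Effect.STIMULATION: "normal",
    Effect.INHIBITION: "tee",
    Effect.BIMODAL: "diamond",
    Effect.FORM_COMPLEX: "none",
    Effect.UNDEFINED: "open",
}


def write_dot(network, highlight: Iterable[str] = ()) -> str:
    """Emit Graphviz DOT text for a network.

    Stimulation edges use normal arrowheads, inhibition tee, bimodal diamond,
    complex membership dashed lines, undefined open arrowheads.  Nodes listed
    in ``highlight`` are filled.
    """
    highlight = set(highlight)
    lines = ["digraph network {"]
    for n in sorted(network.nodes):
        attrs = ['label="%s"' % n]
        if n in highlight:
            attrs += ["style=filled", "fillcolor=lightblue"]
        lines.append(f'  "{n}" [{", ".join(attrs)}];')
    for e in network.sorted_edges():
        attrs = [f"arrowhead={_ARROWHEADS[e.effect]}"]
        if e.effect is Effect.FORM_COMPLEX:
            attrs.append("style=dashed")
        if not e.directed and e.effect is not Effect.FORM_COMPLEX:
            attrs.append("dir=none")
        lines.append(f'  "{e.source}" -> "{e.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
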