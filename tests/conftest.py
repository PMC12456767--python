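import random

import pytest
from hypothesis import settings

import seednet as sn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The bundled 7-edge toy universe (A..F)."""
    return sn.Universe.from_tsv(sn.toy_universe_path())


@pytest.fixture(scope="session")
def complex_toy():
    """Toy universe with a 2-member complex CPLX1 = {P, Q}."""
    return sn.Universe.from_tsv(sn.complex_toy_path())


# ---------------------------------------------------------------------------
# independent oracles, built straight from interaction records
# (never through the package's adjacency indices or search code)


def oracle_adjacency(universe, directed_only=False, signed_only=False):
    adj = {}
    for it in universe.interactions:
        effect_undefined = (
            not it.is_stimulation and not it.is_inhibition and not it.form_complex
        )
        if signed_only and effect_undefined:
            continue
        directed = it.is_directed and not it.form_complex
        if directed_only and not directed:
            continue
        adj.setdefault(it.source, set()).add(it.target)
        if not directed:
            adj.setdefault(it.target, set()).add(it.source)
    return adj


def oracle_simple_paths(adj, source, target, maxlen):
    """Exhaustive DFS enumeration of all simple paths of length <= maxlen."""
    results = []
    stack = [(source, (source,))]
    while stack:
        node, path = stack.pop()
        if node == target and len(path) > 1:
            results.append(path)
            continue
        if len(path) - 1 >= maxlen:
            continue
        for nxt in adj.get(node, ()):  # order irrelevant: exhaustive
            if nxt not in path:
                stack.append((nxt, path + (nxt,)))
    return results


def oracle_min_path_length(adj, source, target, maxlen):
    paths = oracle_simple_paths(adj, source, target, maxlen)
    return min((len(p) - 1 for p in paths), default=None)


def oracle_min_cover_size(coverage, targets):
    """Brute force over every candidate subset; None if uncoverable."""
    import itertools

    candidates = sorted(coverage)
    coverable = set()
    for members in coverage.values():
        coverable |= set(members)
    goal = set(targets) & coverable
    if not goal:
        return 0
    best = None
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            covered = set()
            for c in combo:
                covered |= set(coverage[c])
            if goal <= covered:
                return size
    return best


def random_digraph_universe(rng, n_max=12, p=0.25):
    """A random directed, unsigned universe for oracle comparisons."""
    n = rng.randint(4, n_max)
    nodes = [f"V{i:02d}" for i in range(n)]
    interactions = []
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                interactions.append(
                    sn.Interaction(source=u, target=v, is_directed=True)
                )
    if not interactions:
        interactions.append(
            sn.Interaction(source=nodes[0], target=nodes[1], is_directed=True)
        )
    return sn.Universe(interactions), nodes


@pytest.fixture
def rng():
    return random.Random(20260920)
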