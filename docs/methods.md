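# Methods

## The interaction universe

The universe is a deduplicated store of interaction records indexed for
constant-time neighbor lookup.  Records are keyed by
`(source, target, is_stimulation, is_inhibition, form_complex)`; loading the
same interaction from two resources unions their `references`/`sources`
lists and ORs the direction and consensus flags.  This merge rule is a design
choice: interaction databases disagree on provenance columns far more often
than on sign, and unioning provenance keeps every citation reachable.
Consensus columns are stored and re-exported but never influence traversal or
effect resolution — no principled algorithmic use for them is established, so
they are passive metadata here.

Identifier handling is deliberately minimal: identifiers are opaque strings,
stripped of surrounding whitespace with case preserved.  An optional
two-column mapping table can translate identifiers at load time; no online
symbol→accession mapping is performed, so the package runs fully offline and
results never drift with a web service.

**Traversal rule** (used identically everywhere): directed records are
traversable source→target only; undirected records both ways; `form_complex`
records are membership statements, treated as undirected regardless of their
`is_directed` flag.  The `signed_only` filter drops edges whose resolved
effect is *undefined*; this is what "signed paths" means throughout.

## Graph search

All searches return **simple paths only** and `maxlen` always counts
**edges**.  Neighbor iteration is sorted lexicographically, which makes every
algorithm deterministic without a seed:

* `shortest_paths` — BFS distance labelling capped at `maxlen`, then
  enumeration of all paths along strictly distance-increasing edges.  Returns
  *all* paths of the minimal length, sorted.  `source == target` returns the
  length-0 path.
* `dfs_path` — bounded depth-first search, lexicographic neighbor order,
  first hit returned.  The result is a valid bounded path but not necessarily
  shortest; it exists iff the target is reachable within the bound.
* `upstream_cascades` — layer k maps each direct regulator of the layer-(k−1)
  entities to the set it regulates; each layer is ranked by coverage count
  (descending, ties by identifier).  Undirected edges count as regulation in
  both directions, consistent with the traversal rule.
* `minimal_regulator_cover` — set cover is NP-hard, so two modes are
  provided and reported: exact (ascending-size scan over candidate
  combinations, lexicographic within a size) when there are at most
  `exact_threshold` candidates (default 15, i.e. ≤ 32,768 subsets), greedy
  largest-coverage-first with lexicographic tie-break otherwise.  Targets
  with no regulators are returned in `uncovered`, never silently dropped.

## Strategies

**RPE.** Ordered seed pairs are processed in lexicographic order.  A pair is
skipped when the current network already connects it within `maxlen` — the
bounded check is what makes the completeness guarantee ("every pair with a
universe path within the bound is connected within the bound afterwards")
hold by construction.  The "integration" step adds the direct universe edges
between each newly added node and the nodes that were already present — not
the new node's whole neighborhood, which would collapse RPE into INE.  An
optional `escalate_maxlen` retries unconnected pairs at a longer bound;
escalation is off by default because no single escalation policy suits all
resources.

**INE.** Edge induction runs before any expansion, so directly connectable
seeds stop at iteration 0.  The early-stopping criterion is weak connectivity
(direction-agnostic) among the seeds.  After the loop, pruning removes, to a
fixed point, (a) nodes outside the weakly connected component holding the
most seeds (ties: larger component, then smallest node name) and (b) nodes
with zero incoming edges, where undirected edges give both endpoints a
source.  Seeds are protected from both removals by default — pruning should
never silently delete user input; pass `protect_seeds=False` to override.

**RCE.** The full layered ranking is always returned.  With `attach=True`
only a minimal cover per layer (plus its regulator→regulated edges) is added
to the network rather than all regulators, to avoid hub explosion; the
ranking lets the user attach more by hand.

**MCM.** IN and OUT modes restrict traversal to *directed* interactions —
group-to-group causality is the point of those modes — while ALL uses the
normal traversal rule.  All simple paths up to `maxlen` are enumerated per
ordered pair (OUT: a→b, IN: b→a, ALL: both).  Intermediates form Group C and
are interconnected with the RPE procedure only among themselves.  Group
members absent from the universe are warned and dropped; a fully absent group
is fatal.

**PINC.** Term genes come from a local GAF 2.x or TSV annotation file
(GAF `NOT` qualifier rows are skipped).  Genes present in the universe are
connected to the network via MCM (ALL).  Only the genes that actually ended
up *connected* are merged into the composite; unconnected annotation members
are left out rather than attached as isolates.  At merge, each edge (x→g)
becomes (x→composite) and (g→x) becomes (composite→x); member–member edges
are dropped (they would be self-loops); duplicates collapse; and a
stimulation plus an inhibition inherited for the same partner and direction
collapse to a single *bimodal* edge — both signs are preserved rather than
put to a majority vote, since bimodal already exists in the effect
vocabulary and defers the decision to the Boolean ensemble.

**Complex expansion.** For every network node that is the target of
`form_complex` records, all component nodes and their membership edges are
added, and each component gains its direct universe edges to the nodes that
were already in the network.

Every strategy invocation appends exactly one provenance record (strategy
name, parameters, and outcome details such as unconnected pairs or Group C
membership); the CLI writes the log as a JSON sidecar.

## Boolean export

Rules follow the OR/OR/AND-NOT heuristic; complex nodes AND their members
(membership wins over any causal edge into the complex).  Nodes with no
regulators get the identity rule `N, N` so synchronous states stay
well-defined.  Undefined-effect edges default to activators (with a warning)
so unsigned universes still export; `undefined_as_activator=False` drops them
instead.

A (source, target) pair needs per-member sign resolution when it carries a
bimodal record *or* both a stimulation and an inhibition record; both cases
enter the ensemble enumeration, which orders pairs lexicographically and
counts in binary with activation = 0, so ensemble member k is reproducible
from its index.  The ensemble cap defaults to 1024 models (10 bimodal pairs)
to stop combinatorial blow-up early with a clear error.

The BNET dialect is the boolnet-style `targets, factors` header with `&`,
`|`, `!` and parentheses, one file per ensemble member (`model_<k>.bnet`).
Node names are sanitized to `[A-Za-z0-9_]` with numeric suffixes on
collision; when anything changed, the original→sanitized mapping is written
to `name_mapping.tsv`.  Operands in every OR/AND chain are sorted, so output
is byte-stable; a strict recursive-descent parser re-reads the dialect and a
synchronous one-step evaluator backs the semantics tests.

SIF files are tab-separated `source  relation  target` lines with the five
effect tokens as relations and single-token lines for isolated nodes.  DOT
output maps effects to arrowheads (stimulation: normal, inhibition: tee,
bimodal: diamond, undefined: open) and renders membership edges dashed.

## Synthetic universes

The generator emulates a database-derived resource: exactly `n_edges`
distinct directed pairs sampled without replacement over `n_nodes` entities,
sign classes drawn from configurable proportions (defaults 0.45 stimulation /
0.30 inhibition / 0.05 bimodal / 0.20 undefined — activating edges dominate
curated signaling resources, bimodal records are rare, and a substantial
unsigned fraction exercises the `signed_only` filters), plus optional complex
nodes of 2–3 members.  One `random.Random(seed)` instance drives everything
and categorical draws use integer ranges, so output is bit-identical across
platforms.  It does **not** mimic real interactome degree distributions
(no hubs, no scale-free tails), so passing tests demonstrate algorithmic
correctness, not statistical realism of any biological claim.

## Problem sizes and verification

The audit suite sizes were chosen to exercise the algorithms well past the
toy regime while keeping exhaustive oracles cheap: 200 random digraphs
(≤ 12 nodes, edge probability 0.25) for the shortest-path oracle, 100
instances (≤ 12 candidates) for brute-force cover comparison, 100 random
universes (≤ 30 nodes) for the RPE/INE postconditions, 50 instances each for
MCM directionality, format round trips, and merge conservation, 1000 random
triples for rule semantics, and a 50-seed / 10,000-edge smoke run.  All
oracles are computed directly from the interaction records (plain-dict DFS
enumeration, subset scans, set logic), independent of the package's indices
and search code.

## Known limitations

* No live database clients: resources arrive as local delimited files, and
  ontology annotations as local GAF/TSV.  Column maps adapt foreign layouts.
* Identifiers are opaque; cross-namespace mapping is the user's job.
* Only simple paths are searched; regulatory loops appear in the network when
  their edges are induced, but cycles are never traversed during search.
* Boolean rules are a heuristic starting point.  Without data constraints the
  ensembles usually lack biologically meaningful attractors; no attractor
  computation or model refinement is included.
* MCM enumerates *all* bounded simple paths per group pair, which grows
  quickly with `maxlen`; bounds above 4 on dense universes are expensive.
* DOT emission is plain text; rendering and PDF export are out of scope.
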