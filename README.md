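# seednet

**seednet** assembles signed, directed molecular networks from a list of seed
entities (genes, proteins, phosphosites) and a tabular prior-knowledge
interaction resource — the *universe*.  It automates what a curator does by
hand when building a problem-specific signaling network from a general
interaction compendium: look up the seeds, find the paths and regulators that
connect them, attach phenotypes, and export the result for downstream
topological analysis (SIF for Cytoscape), visualization (Graphviz DOT), or
logical modeling (Boolean rule ensembles in BNET format).

It is aimed at systems biologists who have a gene signature — top hits from a
differential-expression analysis, a curated marker list, a set of drug
targets — and want a mechanistic draft network connecting it, without writing
graph-traversal code or web-scraping interaction databases.

## The model

The universe is a set of interaction records with at minimum `source` and
`target` columns; optional columns (`is_directed`, `is_stimulation`,
`is_inhibition`, `form_complex`, consensus flags, `references`, `sources`)
default to false/empty, which yields undirected, unsigned edges.  Each record
resolves to one of five effects: *stimulation*, *inhibition*, *bimodal*
(reported as both), *form_complex* (membership, non-causal), or *undefined*.
Directed records are traversed source→target; undirected and complex records
are traversed both ways.

Five deterministic strategies grow a network from the seeds:

| strategy | what it does |
|---|---|
| **RPE** (reciprocal pathway extension) | for every ordered seed pair without a path, add all minimal-length universe paths (BFS) or one depth-first path within a length bound, then wire each new node to the existing network |
| **INE** (iterative neighbor expansion) | add each frontier node's neighbors and all induced edges, iterating until the seeds share one component; prune dangling and source-less nodes |
| **RCE** (regulatory cascade exploration) | rank upstream regulators of chosen output nodes by how many outputs they regulate, layer by layer; optionally attach a minimal regulator cover |
| **MCM** (module connection mapping) | enumerate bounded paths between two node groups (IN / OUT / ALL modes); intermediates form "Group C" and are interconnected by RPE |
| **PINC** (phenotype integration) | fetch the genes annotated to an ontology term (local GAF/TSV), connect them via MCM, and merge the connected ones into a single composite phenotype node that inherits their edges |

For logical modeling, each node's Boolean rule chains its activators with OR,
its inhibitors with OR, and combines the groups with AND NOT:

    node = (A1 | ... | Am) & !(I1 | ... | In)

Complex nodes AND their members.  Every bimodal interaction doubles the model
space, so a network with B bimodal edges exports as an ensemble of exactly
2^B BNET models, one per sign assignment.

All tie-breaks are lexicographic, so every strategy and exporter is
deterministic — identical inputs give byte-identical outputs.

## Worked example

The bundled toy universe has seven directed interactions over six entities
(A–F).  Connect seeds A and C with RPE, bounded at three edges:

```sh
seednet build \
    --universe src/seednet/data/toy_universe.tsv \
    --seed-node A --seed-node C \
    --strategy rpe:maxlen=3,algorithm=bfs \
    --output sif=toy_net.sif --output dot=toy_net.dot
```

prints

```
nodes=5 edges=6 seeds=2
```

and `toy_net.sif` contains

```
A	stimulation	B
A	stimulation	D
B	inhibition	C
C	inhibition	E
D	stimulation	C
E	stimulation	A
```

A→C was connected through both minimal paths (A→B→C and A→D→C, adding B and
D), and C→A through C→E→A (adding E); F stays out because it lies on no
seed-connecting path.  The same run from Python, continued into a Boolean
export:

```python
import seednet as sn

uni = sn.Universe.from_tsv(sn.toy_universe_path())
net = sn.Network(["A", "C"], uni).connect_rpe(uni, maxlen=3)
ensemble = sn.enumerate_ensemble(net)      # no bimodal edges -> 1 model
sn.write_bnet(ensemble, "toy_models")
```

which writes `toy_models/model_0.bnet`:

```
targets, factors
A, E
B, A
C, D & !B
D, A
E, !C
```

C's rule reads: C is ON when its activator D is ON and its inhibitor B is
OFF.  A JSON provenance sidecar next to the first output records every
strategy invocation and its parameters.

A synthetic universe generator (`seednet gen-universe`, or
`seednet.generate_universe` in Python) produces seeded random resources with
configurable sign proportions and complex records, for testing and
benchmarking without any database download.

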