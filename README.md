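# metamap

Flow-based community detection that blends network structure with node
metadata through **metadata-dependent encoding of random walks**.

Many systems — social networks with gender or role labels, mobility
networks with socioeconomic indicators, power grids with energy prices —
carry node metadata whose relationship to the network's large-scale
structure is *nonlocal*: nodes with similar metadata may sit far apart in
the graph.  Methods that couple metadata only to immediate neighbours
(stochastic block models with covariates, content-augmented map
equations) can subdivide structural communities by metadata but cannot
merge distant, similar nodes.  metamap is for network scientists who want
a single tunable dial between purely structural communities and purely
metadata-defined ones, including everything in between.

## The model

Given a connected weighted graph *G* with column-stochastic transition
matrix π<sub>jk</sub> = w<sub>kj</sub> / Σ<sub>j</sub> w<sub>kj</sub> and
stationary visit rates *p<sub>i</sub>*, consider a fragmented random walk
that restarts at node *i* with probability *p<sub>i</sub>*, walks, and at
each arrival node *j* *encodes* the transition *i → j* with probability
ε<sub>ij</sub>, terminating on success.  Aggregating encoded transitions
yields the **encoding graph** *E* = {e<sub>ij</sub>}, a flow graph with
Σ<sub>ij</sub> e<sub>ij</sub> = 1, computed here in closed form from the
transient series

&nbsp;&nbsp;&nbsp;&nbsp;e<sub>ij</sub> = Σ<sub>t≥1</sub> ε<sub>ij</sub> p<sub>j</sub>(t|i),&nbsp;&nbsp;&nbsp;
P(t|i) = Π̃<sub>i</sub> P(t−1|i),&nbsp;&nbsp;&nbsp;
π̃<sub>jk|i</sub> = π<sub>jk</sub>(1 − ε<sub>ik</sub>)

(summed exactly via the fundamental matrix), or stochastically by
simulating the walks.  Encoding probabilities come from metadata
*f*: for categories, ε<sub>ij</sub> = *p* if *f<sub>i</sub>* = *f<sub>j</sub>*
and *p/c* otherwise (assortative for *c* > 1, neutral at *c* = 1,
disassortative for *p* < *c* < 1); for real values,
ε<sub>ij</sub> = *s*·exp(−|f<sub>i</sub> − f<sub>j</sub>|/*b*)·*p* + (1 − *s*).
With ε ≡ 1 the encoding graph reduces to the one-step stationary flow
graph, recovering classical flow-based community detection.

Communities are found by minimizing the two-level **map equation** on the
flows of *E* directly:

&nbsp;&nbsp;&nbsp;&nbsp;L(M) = q H({q<sub>m</sub><sup>enter</sup>/q}) +
Σ<sub>m</sub> p<sub>m</sub><sup>tot</sup> H({q<sub>m</sub><sup>exit</sup>, p<sub>j∈m</sub>}/p<sub>m</sub><sup>tot</sup>)

with a seeded Louvain-style search.  Two diagnostics relate partitions to
metadata: the mixing ratio *r<sub>m</sub>* (mean per-category fraction of
same-category pairs co-assigned to one community) and the class-overlap
matrix m<sub>αβ</sub>.

## Worked example

The built-in three-clique benchmark (K9 ∪ K15 ∪ K21, three balanced
metadata classes per clique, a few inter-clique bridges):

```python
import metamap as mm

graph, meta = mm.clique_benchmark(seed=1)
grid = [mm.CategoricalParams(p=1.0, c=1.0),
        mm.CategoricalParams(p=0.5, c=50.0),
        mm.CategoricalParams(p=0.1, c=100.0)]
table = mm.sweep(graph, meta, grid, n_trials=100, seed=42)
print(table.to_string(index=False))
```

prints

```
  p     c  codelength  n_modules     r_m
1.0   1.0    4.314454          3 0.32381
0.5  50.0    3.563574          9 0.32381
0.1 100.0    4.015268          3 1.00000
```

Neutral encoding (p=1, c=1) finds the three cliques — pure structure;
each category is spread over the three cliques, keeping about a third of
its pairs together (r_m ≈ 0.32).  At p=0.5, c=50 each clique splits into
its three classes (9 modules).  At p=0.1, c=100 walkers roam far before
encoding and the three classes themselves become the communities:
every category sits in a single module, r_m = 1.

The same workflow is available from the shell:

```sh
metamap generate --model clique --seed 1 --out bench
metamap encode --graph bench.edges.tsv --metadata bench.meta.tsv \
        --p 0.5 --c 50 --out flows.tsv
metamap partition --flows flows.tsv --n-trials 100 --seed 3 --out part.tsv
metamap metrics --partition part.tsv --metadata bench.meta.tsv --out metrics.json
```

and as one JSON-configured run: `metamap pipeline --config config.json`.

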