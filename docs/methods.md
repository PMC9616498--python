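# Methods

## The walk process and the encoding graph

metamap models a fragmented random walk on a connected weighted graph
*G*.  A walk restarts at node *i* drawn proportionally to the stationary
visit rates *p_i* of the standard (metadata-ignorant) walk, steps by the
column-stochastic transition matrix π_jk = w_kj / Σ_j w_kj, and at each
arrival node *j* performs an encoding trial with probability ε_ij that
depends only on the metadata of *i* and *j*; on success the ordered pair
(i, j) is recorded and the walk terminates.  The encoding graph
E = {e_ij} collects the per-pair encoding probabilities; its total flow
is 1 and its per-source flow Σ_j e_ij equals p_i, because every started
walk encodes exactly once (almost surely, given the ε floor below).

No encoding trial occurs at the walk's origin at t = 0; the first trial
happens after the first step.  This follows the verbal process
(start at *i*, step to *j*, encode with probability ε_ij) rather than a
literal t = 0 expansion of the transient recursion, which would insert a
survival factor (1 − ε_ii) before any step.  The two conventions differ
only by O(ε_ii) factors on first-return flows.

### Closed form

For source *i*, survivor mass propagates by v(t+1) = Π̃_i v(t) with
π̃_jk|i = π_jk (1 − ε_ik) and v(1)_j = p_i π_ji, while
e_ij = Σ_{t≥1} ε_ij v(t)_j.  Because Π̃_i is a strict contraction
(every ε_ik > 0), the series is geometric and is summed exactly by one
linear solve per source:

    u = (I − Π̃_i)^{-1} v(1),        e_ij = ε_ij u_j .

This fundamental-matrix summation is the default (`method="solve"`): it
is exact and its cost is independent of how small the encoding
probabilities are.  A truncated power-series iteration
(`method="series"`, tolerance `tol` on the surviving mass, cap `t_max`,
error if more than 1% of the source mass is unencoded at the cap)
remains available and is tested to agree with the solve to 1e-10; for
small ε the series needs on the order of 1/min(ε) iterations per source,
which is why it is not the default.  Either way each source row is
rescaled to sum exactly to p_i, so both conservation invariants hold to
machine precision.

### Monte Carlo

`monte_carlo_encoding_graph` simulates the walks directly (vectorized
over all active walks) and normalizes recorded counts by the number of
recorded walks, so the total flow is exactly 1.  Walks exceeding
`max_steps` (default 10^4) are discarded with a warning; a discard
fraction above 0.1% is an error.  The Monte-Carlo route exists as an
independent oracle for the closed form; tests compare the two within a
*simultaneous* binomial band: per-flow tolerance z·SE + 3/n_walks with
z = Φ⁻¹(1 − 0.01/(2m)) over the m compared pair flows.  A per-flow
3-SE band would be expected to fail somewhere for almost any seed once
m ≈ 2000 flows are compared at once, and the normal approximation is
invalid for flows with expected counts of order 1 — hence the
multiplicity correction and the 3-count continuity allowance.

## Encoding probabilities

Categorical (parameters p, c): ε = p for same class, p/c otherwise;
c > 1 assortative, c = 1 neutral (metadata-blind), p < c < 1
disassortative.  The same rule is used unchanged for more than two
categories.

Continuous (parameters p, b, s): the literal form
ε = s·exp(−|Δf|/b)·p + (1 − s) is the default.  At s = 1 and binary
metadata one unit apart it equals the categorical model with
c = e^{1/b}.  For s < 1 the literal form gives ε(Δf=0) = s·p + 1 − s,
i.e. not p; a self-consistent factored variant
ε = p·(s·exp(−|Δf|/b) + 1 − s) is selectable (`form="factored"`).  Both
readings are preserved deliberately; neither is silently "fixed".
Metadata is z-scored (population SD) by default so that b is measured in
SDs; ε_ii uses ε(f_i, f_i) = p (at s = 1), i.e. returns to the origin are
ordinary arrivals.

All ε are clamped to [1e-12, 1] before walk dynamics: an exactly-zero ε
along a whole trajectory would make walks never terminate, and the floor
guarantees almost-sure encoding while perturbing flows negligibly.

## Map equation and optimizer

The two-level codelength is evaluated on the flows of E directly — node
visit rates are column sums of E, module enter/exit flows are raw
inter-module flow sums; no flow re-modeling or teleportation is applied.
The index codebook uses module *enter* flows and each module codebook
includes the module *exit* term (the standard directed convention; for
the symmetric E arising from undirected graphs with symmetric ε the
distinction vanishes).  Zero-rate terms contribute zero bits.

The optimizer is a seeded Louvain-style search: starting from singleton
modules, greedy single-node moves to modules sharing nonzero flow
(strict gain > 1e-12, ties broken toward the lowest module id, node
order reshuffled per pass from the trial's seeded stream), aggregation
of modules into super-nodes, recursion, and node-level fine-tuning after
unfolding.  The best of `n_trials` restarts is returned; runs are
deterministic given (seed, n_trials).  With `max_modules` set, module
pairs are merged greedily (least codelength increase) until the cap is
met — a two-level stand-in for restricting the search to a fixed number
of top-level modules.  On ≤8-node flow graphs the search attains the
exhaustive (Bell-enumeration) minimum in ≥95% of random instances; the
remaining cases are genuine local optima of the greedy move set, reported
by the acceptance test rather than hidden.  Multilevel (deeper than
two-level) coding is out of scope.

Partition similarity is adjusted mutual information (scikit-learn),
clipped to [0, 1]: 1 iff identical up to relabeling, 0 in expectation
for independent partitions.

## Metrics

Mixing ratio: r_m = (1/N_cat) Σ_k a_k / (n_k(n_k−1)/2), where a_k counts
same-community pairs of category k.  Categories with a single node have a
vacuously satisfied constraint; their term is defined as 1 and a warning
is issued (the alternative — counting them as 0 — would bias r_m
downward for reasons unrelated to mixing).  Continuous metadata must be
discretized first; `quantile_bin` (quartiles by default) is provided.
"Number of categories" is the normalizing count in r_m, distinct from
the number of communities.

Class overlap: m_αβ = (N_α+N_β)^{-1} Σ_c (N_cα+N_cβ)·[both classes
present in c], with m_αα = 1 identically and m_αβ = 0 iff no community
mixes the two classes; m̃ is the row-normalized form.

## Synthetic benchmarks

Clique benchmark: cliques K9, K15, K21 (unit weights), three classes
assigned round-robin inside each clique (exactly one third each), and
three unit-weight bridges per clique pair whose endpoints share a
(seeded) random class.  Three bridges per pair is a deliberate choice:
with a single bridge, escape from a clique is so rare that the
metadata-dominated regime (p = 0.1, c = 100) cannot outweigh the
clique-by-class split — the 9-module partition stays strictly shorter —
whereas with three bridges all three regimes (3 structural, 9
clique-by-class, 3 class-pure modules) are stable across seeds.  The
count is configurable for sensitivity checks.

Ring model: N nodes in N_c equal communities on a ring (defaults
N = 240, N_c = 8 — eight communities of 30 is a choice of this package;
community counts in that range behave equivalently).  Unit-weight links
appear independently with probability p1 within a community and p2
between ring-adjacent communities only (defaults 0.6 and 0.2).  Metadata
initially equals the planted community id; reshuffling performs n_steps
independent uniform draws of node pairs whose planted communities are at
ring distance exactly d_c (shortest arc) and swaps their metadata, so
category counts are preserved and r_m terms stay comparable across
reshuffling levels.  Disconnected draws are regenerated from child seeds
(bounded retries).

What the generators emulate — and what they do not: both produce
unweighted, undirected, assortatively planted structure with balanced
categories.  Real systems have skewed degree and category-size
distributions, weighted and possibly directed edges, and metadata only
partially aligned with any planted structure; passing tests on these
benchmarks therefore demonstrate correctness of the machinery and the
qualitative structure-to-metadata interpolation, not performance claims
on real data.

## Problem sizes and numerical choices

Default problem sizes used by the test and acceptance suites: the
45-node clique benchmark (100 optimizer trials), a 240-node ring sweep
over c ∈ {1, 2, 5, 10, 20, 50, 100, 1000} at p = 0.5 with 112 reshuffles
at d_c = 1 (10 trials per grid point), 10^6 Monte-Carlo walks for oracle
comparisons, and 100 random ≤8-node instances for exhaustive-optimality
checks.  Closed-form construction is dense per source (N ≤ a few
thousand is comfortable); flows are stored sparsely with dense (absent =
0) semantics.  Flow TSV files carry 17 significant digits and round-trip
bit-stably.  Stationary distributions use the closed form
(strength / total strength) for undirected graphs and power iteration
(L1 residual < tol) for directed ones; non-primitive directed graphs are
an error, never silently regularized by teleportation.  The single
long-walk (non-restarting) encoding variant is deliberately not
implemented: it depends on the starting node and is superseded by
stationary restarts.

## Known limitations

- Two-level coding only; deeply nested module hierarchies are
  approximated by the `max_modules` cap.
- Scalar metadata only (categories or one real value per node).
- The greedy optimizer trades exactness for speed; small instances are
  verified against enumeration, large ones rely on restarts.
- Dense per-source solves make closed-form construction O(N·N²); for
  graphs beyond ~10^4 nodes the Monte-Carlo route is the practical one.
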