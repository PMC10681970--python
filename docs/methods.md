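# Methods

## The density matrix

The package characterizes the relationship between two communities (blocks)
of a partitioned graph purely through the edge-density matrix ω: the number
of existing links between (or within) blocks divided by the number of
possible such links. For a directed multigraph with adjacency counts
A_ij ∈ ℕ,

    ω_rs = Σ_{i∈r, j∈s} A_ij / (N_r N_s)              for r ≠ s,
    ω_rr = Σ_{i,j∈r, i≠j} A_ij / (N_r (N_r − 1)),

and the within-block denominator is ½ N_r (N_r − 1) for undirected graphs
(each unordered pair counted once). Because the possible-link counts
exclude i = j, self-loop multiplicities are dropped from the numerators as
well; loaders flag their presence. Multigraph densities may exceed 1 and
are returned unclamped — all downstream logic is rank-based, so no
normalization is needed or wanted.

**Exact arithmetic.** Every ω entry is a `fractions.Fraction`. The
classifier's conditions are strict inequalities, and the package treats an
exact tie among consulted densities as its own outcome (DEGENERATE). That
decision is only meaningful if equality is decidable, which floats do not
offer: two genuinely equal ratios of integers can differ in floating point
and vice versa. Float inputs are still accepted by the pair classifiers
(useful for the null model, where ties have probability zero) and are
compared exactly as given.

**Singleton blocks.** ω_rr for a block of size 1 is 0/0. There is no
principled value, so the entry is stored as 0 with a per-block flag, a
warning is logged, and any pair consulting a flagged cell is reported
DEGENERATE rather than typed.

**Canonical ordering.** Block labels are ordered so that ω_rr ≥ ω_ss for
r < s, ties broken by label order (logged). Classification additionally
re-canonicalizes each pair by its own two self-densities, which is the
minimal requirement of the type conditions and cannot disagree with the
global sort.

## The type catalog

A pair in canonical order is typed by strict inequalities on the consulted
densities (three undirected, four directed; see the README for the
conditions). Enumerating strict orderings under the canonical constraint
gives 3 undirected configurations U1–U3 (one per type) and 12 directed
configurations D1–D12 (assortative 2, core–periphery 4, disassortative 2,
source–basin 4). The conditions partition the orderings: exactly one holds
for every strict ordering after canonicalization, and swapping which block
is called r leaves the type unchanged. D-labels are assigned by
lexicographic order of the rank vector of (ω_rr, ω_rs, ω_sr, ω_ss); the
labels are this package's indexing convention, and the stable, documented
contract is the type, not the D-number.

**Ties.** Exact ties are reported as DEGENERATE, a fifth category: it
contributes to fraction denominators, never competes for dominance, and is
excluded (numerator and denominator) from the nonassortative fraction.
Sparse empirical graphs produce many exactly-zero densities; any silent
tie-break would bias type fractions precisely there.

## Profiling and the survey table

A network's profile classifies all B(B−1)/2 pairs and tallies exact
fractions per category. The dominant type is the argmax over the four named
types; exact ties are reported as TIE with all maximizers listed, and
aggregation across networks lets ties withhold dominance mass rather than
splitting it. Per-community summaries (for interpreting a source–basin
pair) report block size, multiplicity-weighted mean in/out degree,
membership in the global top-k out-degree set (ties at rank k broken by
node label, logged), and attribute fractions over the block members present
in the attribute table.

## Null model

The baseline for type fractions draws every ω entry i.i.d. Uniform(0, 1)
(upper triangle mirrored when undirected), canonicalizes, classifies, and
averages over replicates. Since the classifier consults only rankings, any
continuous i.i.d. law yields identical type probabilities; the uniform is a
concrete choice, not an assumption. For B = 2 the analytic fractions follow
from configuration counting: directed (A, CP, D, SB) = (2, 4, 2, 4)/12,
undirected (1, 1, 1)/3. Both the per-replicate standard deviation (the
spread) and the standard error of the mean are reported. All draws flow
from one explicit seed through `numpy.random.default_rng`; equal seeds give
bit-identical estimates.

## Planted-partition generator

The generator inverts the density computation in expectation: multiplicity
of each ordered (directed) or unordered (undirected) pair of distinct nodes
in blocks r, s is Bernoulli(ω_rs) (simple graph, default) or Poisson(ω_rs)
(multigraph, honors densities above 1). The Bernoulli default suffices
because classification is rank-based and unaffected by the multigraph
extension. Degree heterogeneity is deliberately not modelled: the
classifier consumes only ω, so targeting ω directly is the smallest
sufficient test bed. Consequence: passing recovery tests demonstrate that
the pipeline recovers planted density structure, not that any detector
finds such partitions in degree-heterogeneous real networks — detector
quality is explicitly out of scope.

`fixture_for_configuration` realizes a requested configuration (or a
representative of a requested type) as a two-block ω whose ranked entries
are the arithmetic sequence margin·(n, n−1, …, 1), n = 4 directed /
3 undirected, so consecutive ranks are separated by exactly the margin.
Recovery is governed by binomial noise on ω̂: at block size 300 a cross
density p has standard error √(p(1−p))/300 ≲ 0.0017, so a margin of 0.05
is ~30 standard errors and recovery at ≥95% of seeds has large headroom.
Source–basin (and core–periphery as a distinct configuration set) requires
direction; requesting it undirected is a usage error.

## Detectors and the sweep

Community detection is out of scope; the package defines an adapter
contract (graph, optional B, seed → partition) with four implementations:
the planted-truth oracle (below the planted B it keeps the first B−1
blocks in label order and merges the rest — a deterministic stand-in for
the coarser partitions a real method reports), a fixed partition file, an
external subprocess (argv + [edgelist, B, seed, out_tsv]), and a seeded
greedy single-node-move maximizer of directed (Newman–Leicht) modularity
kept for convenience on small graphs. The greedy detector runs one pass
sequence per seed; multi-restart consensus is the caller's concern.

The sweep procedure increases B from 2 and stops at the first B whose pair
classifications contain any type other than assortative or DEGENERATE,
reporting that B, the triggering pairs and types, and the per-B profiles —
the smallest partition in which nonassortative structure appears. If none
appears by B_max it reports exhaustion.

## Numerical and scale choices

- All randomness flows from explicit integer seeds; no global RNG state.
- Exact rational arithmetic everywhere a tie decision could be consulted;
  floats only in Monte-Carlo summaries and degree means.
- Problem sizes in the shipped tests: planted recovery uses blocks of 300
  nodes with 100 replicates per directed configuration; the null model is
  checked at 100,000 replicates (3 Monte-Carlo standard errors); the sweep
  demonstration uses three blocks of 100 nodes. These sizes put the checks
  far outside the noise floor while keeping the suite fast.
- Modularity in the greedy detector uses penalty normalization M = m
  (directed) or 2m (undirected) so the single-node move gains are exact
  deltas of the reported modularity.

## Limitations

- Pairwise only: types are defined per block pair; no higher-order
  community-relationship patterns.
- ω is a descriptive density, not a fitted block-model parameter; no
  degree correction or likelihoods.
- Edge multiplicities must be integers; weighted graphs are rejected.
- No bipartite, multilayer, or temporal graph support.
- The survey machinery aggregates whatever partitions it is given; the
  quality of empirical conclusions rests on the external detector.
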