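# Methods notes

## Network model

A system is a typed two-level graph: actor nodes with a category
attribute (`MOU`, `FIRST_GEN`, `SECOND_GEN`, `OTHER`) and an optional
founding year (metadata only; nothing temporal is modelled), ecosystem
nodes with an optional watershed label, and three undirected edge layers
(social, eco, membership). Water flow is directional in reality, but all
building blocks are defined through *connectivity*, so eco edges are
stored undirected; a per-edge `direction` annotation is accepted and
preserved by I/O and ignored by every analysis. Multiplicity is not
modelled: a tie or membership listed twice collapses to one edge, and a
pair reported by either party yields one undirected edge (the OR-rule is
applied upstream of the loader). Validation is separated from
construction so invalid networks can be represented and diagnosed;
loaders hard-fail on referential errors naming the offending row.

## Building blocks

Ten templates *a*–*j*, each with typed slots, required edges, forbidden
edges, named positions and an explicit symmetry group (validated for
identity, closure, type preservation and edge-set invariance). Layers a
block does not mention are unconstrained — e.g. the open triad *e*
places no constraint on memberships, which is what lets its hub tallies
count regardless of the hubs' lake ties. Two design points were genuinely
open and are resolved as follows:

* Blocks *a* and *i* complete the 2×2 designs of their families: *a* =
  shared lake *with* a collaboration tie (complement of *b*), *i* =
  parallel work on connected lakes *without* a tie (complement of *h*;
  *j* covers tie-without-connection). The fully disconnected parallel
  variant (no tie, unconnected lakes) is the null category and is not a
  block.
* H1 fit labels: good = {*a*, *c*, *h*}, poor = {*b*, *d*, *i*}; the
  communication blocks *e*, *f*, *g*, *j* are neutral for H1 and feed the
  positional rules instead.

Both are overridable: the catalogue serializes to a documented JSON
schema and `load_catalog` revalidates everything, so amended templates
drive the whole pipeline unchanged.

## Census semantics

The counting unit is a symmetry-distinct injective slot assignment; the
canonical representative of an orbit is the lexicographically smallest
assignment tuple in slot order, and enumeration order is sorted, so
outputs are bit-for-bit reproducible. Per-assignment counting (rather
than per node subset) makes positional tallies consistent — a hub with
degree \(k\) heads \(\binom{k}{2}\) open triads. Because assignments are
injective and symmetries preserve slot types, every orbit has size
exactly \(|\mathrm{sym}|\), so the counts-only fast path counts all
assignments and divides. `counting="node_sets"` is exposed as a
documented switch; for the default ten templates the two modes coincide
(no template admits two non-symmetric assignments on one node set), which
is why the switch is demonstrated in tests with a custom template. The
backtracking enumerator orders slots to maximize required-edge anchoring
and intersects neighbour sets; a brute-force census (plain filter over
all injective tuples) is kept as an independent oracle and the two are
asserted equal on hundreds of random networks.

## Null model

The eco layer is always frozen: the landscape is a physical constraint
and the scientific question is how actors arrange themselves on it.
Default scheme: social `fixed_count_shuffle` (uniform simple graph with
the observed edge count) and membership `actor_degree_preserving` (each
actor's lake set redrawn uniformly at its observed size). This preserves
each group's workload and the overall collaboration volume while
randomizing partner choice and lake choice. Alternatives are selectable
per layer — `degree_preserving_swap` (double-edge swaps, ≥10×|E|
successful swaps attempted with a bounded retry budget) and
`both_degrees_preserving` (bipartite checkerboard swaps) — and every run
manifest records the scheme, R, seed and an input digest.

Significance uses empirical one-sided p-values with the +1 correction
(never zero), two one-sided tests rather than a doubled two-sided p
because the codes are signed; over-representation takes display
precedence (both tails cannot fire for R ≥ 19). `method="zscore"` gives a
normal-approximation variant for comparison with bell-curve style
reports; it is never the default. Replicate seeds are drawn from a
single generator seeded by the user, and replicates are censused with
the same engine as the observed network, so `null_distribution` is fully
reproducible; a consistency test pins replicate 0 to a standalone
`randomize` call with the same seed.

Because motif counts are small integers, the empirical p-value is
conservative under ties: for blocks whose null distribution concentrates
on few values, the realized rejection rate at nominal 0.05 can be far
*below* 0.05 (it can never validly exceed it). The calibration tests
therefore check validity — per-tail rejection rates under the neutral
generator must not exceed the binomial 99% upper bound of nominal 0.05 —
rather than two-sided agreement with 0.05, which discreteness makes
unattainable for the sparse blocks.

## Positional analysis

For each occurrence and each reportable position, the occupying actor's
tally is incremented; symmetric slots pool into one position (*e-2* pools
the two peripheral slots), giving the conservation law
Σ_actors tally(block, pos) = count(block) × multiplicity(pos). Shares are
row-normalized per (block, position) and hence not comparable between
rows; category shares sum actor shares. Shares of never-occurring blocks
are NaN, surfaced as such by `category_share` rather than crashing. The
"share" a category holds of a position is an occurrence share, not a
share of distinct actors — the alternative reading can be recovered from
the long-format export.

## Hypothesis rules

The hypotheses are narrative in origin; the report codifies them as
explicit rules (stated in its header) with every threshold in
`RuleConfig`, using the focal category's actor share as the default
baseline: H1 from significance codes on fit-labelled blocks (signals for
vs. against); H2 from the focal share of the good-fit actor positions
*c-1* and *h-1*, with a partial verdict when focal actors appear in
every lake-chain collaboration without driving *c*; H3 from the focal
share of *g-2* (vs. baseline) together with a hub majority at *e-1*
(share > max(baseline, 0.5)). Verdicts are pure functions of their
inputs, cite evidence rows, and degrade to `indeterminate` (never a
crash) when the referenced blocks do not occur.

## Synthetic generator

The landscape partitions `n_lakes` as evenly as possible into
`n_watersheds` edge-disjoint components, each a path ("chains") or a
uniform random labelled tree; a cross-watershed link probability exists
and defaults to 0. Groups then draw a portfolio size (default
distribution P(1)=0.75, P(2)=0.20, P(3)=0.05 — a documented guess at a
realistic workload mix giving ≈30 memberships over 29 lakes), a first
lake (uniform, or from occupied lakes with probability
`shared_lake_pref`), and further lakes from the eco-neighbours of their
current lakes with probability `chain_pref` (negative values avoid
neighbours — the anti-chain extension used for misfit power checks),
falling back to uniform. Social ties are placed sequentially up to
`mean_ties_per_group × n/2` edges: with probability `mentor_pref` a
2nd-generation→MOU attachment, otherwise a uniform draw over absent
pairs. Defaults (23 groups split 3/7/13, 29 lakes, 3 watersheds,
chain_pref 0.9, mentor_pref 0.8, shared_lake_pref 0.1, 2.4 ties per
group) mirror the marginal structure of the study system the package was
designed around.

**Neutrality argument.** With all three preferences at 0 the social layer
is built by sequential uniform draws over absent pairs — every m-subset
of pairs is equally likely, i.e. exactly the `fixed_count_shuffle` null —
and each portfolio is a sequence of uniform draws without replacement,
i.e. a uniform k-subset, exactly the `actor_degree_preserving` null.
Observed and null censuses are then exchangeable, which is what makes the
neutral generator a genuine type-I baseline; the calibration and
law-equality tests check this empirically.

What the generator does **not** emulate: temporal growth of the group
population, interview-derived tie weights or directions, geographic
distance (only topological adjacency), and lake-side popularity effects
beyond `shared_lake_pref`. Passing tests on synthetic draws therefore
show the machinery is correct and calibrated under these mechanisms, not
that any particular real system fits them.

## Problem sizes and numerical choices

The test suite uses: 200 random ≤8×8 networks for oracle equivalence;
all 2^15 three-actor/three-eco networks for the partition identities;
200 generator seeds × R=200 for calibration; 50 seeds × R=1000 per
planted-signal direction (chain preference ρ=1 with two lakes per group;
anti-chain ρ=−1 with four). The anti-chain configuration uses four lakes
per group because on a 29-lake forest ~94% of random lake pairs are
already unconnected: with sparse portfolios the null cannot be beaten,
while at four lakes per group the null chain-pair mean is ≈8.8 and
P(null d ≥ observed) = P(null chain count = 0) ≈ 1.4·10⁻⁴ — a power
analysis done from the closed-form means, not by tuning against test
outcomes. The acceptance script uses 60 oracle networks, 25 seeds per
planted direction at R=1000, and 100×R=150 for calibration. Degenerate
inputs are defined behaviour throughout: empty networks census to zero,
constant nulls give p=1 and code `0`, zero-count shares are NaN, and
swap-based randomizers bound their retry budgets.

## Known limitations

Enumeration is exact and unsampled, appropriate for networks of tens of
nodes per type; it is not meant for large graphs. The demo network is a
stylized reconstruction — its numbers characterize the reconstruction,
not the unpublished observed system. No ERGM-style inferential model is
provided (out of scope by design); the null-model comparison is
descriptive-inferential in the permutation-test sense only.
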