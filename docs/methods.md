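# Methods

## Model

Genomes are modelled as matchings on gene extremities.  Gene *i*
(1-based) has tail vertex 2*i* − 1 and head vertex 2*i*; adjacencies are
stored as sorted vertex pairs, and gene arcs are carried only to convert
to and from gene orders — comparisons ignore them.  Augmentation adds
one telomeric vertex per telomere and *f* fictional vertices (paired
consecutively; the pairing is a free choice and this one is
deterministic), producing a perfect matching with
*n* = 2*g* − *a* + *f*/2 adjacencies on 2*n* vertices.

The evolution model selects one of the *n*(*n* − 1) DCJs uniformly at
each step: an unordered pair of distinct adjacencies and one of two
rewirings.  This move set deliberately includes moves that only touch
telomeric/fictional adjacencies and leave the observable genome
unchanged; *f* is a model parameter that shifts the stationary telomere
count.  The simulator draws a uniform random adjacency (via a uniform
random vertex), a second one uniformly among the rest, and a fair
rewiring bit — exactly the uniform move law, without enumerating moves.
DCJs never change the vertex set, so the total count of
telomeric-plus-fictional vertices is invariant (their kinds may swap).

## Expected breakpoints and the closed-form estimator

A breakpoint of G₁ with respect to G₂ is an observed adjacency of G₁
absent from G₂.  Per adjacency, the per-step cut probability is
p = 2/*n* and the no-rejoin probability is q = 1 − 1/(*n*(*n* − 1));
iterating P_k = P_{k−1}(q − p) + p from P₀ = 0 and summing the geometric
series gives

E(B_k) = a(2n−2)/(2n−1) · (1 − (1 − 1/(n−1) − 1/n)^k).

The package carries both the closed form and the recurrence (they agree
to ~1e−14 relative on an a × n × k grid) and, decisively, checks the
closed form against an exhaustive exact computation: the full DCJ
Markov chain over all (2n−1)!! perfect matchings for n ∈ {3, 4},
evolved in rational arithmetic — equality is literal, not approximate.

Inversion of E(B_k) at an observed B gives the estimator k̂.  B at or
beyond the stationary value a(2n−2)/(2n−1) returns a flagged saturated
sentinel (k̂ = ∞) rather than raising: saturation at k = O(n log n) is
expected behaviour, and batch experiments must run through it.
Non-integer B is accepted so that averaged curves can be inverted.

When comparing two arbitrary genomes, *f* must make a common
augmentation possible; the default is the lower bound 2|a₁ − a₂|
(DCJs preserve the telomeric+fictional vertex count, so fictional
elements must absorb the telomere-count difference).  The admissible
upper end of the bracket — of the order of the equilibrium telomere
count — is left configurable and deliberately unresolved.

## Breakpoint graphs

The union of two augmented matchings on a shared vertex set decomposes
into cycles alternating between the genomes; cycle length is counted as
the number of adjacencies of one genome on the cycle, so lengths sum to
n and a trivial cycle (two parallel edges) has length 1.  The *real*
breakpoint graph uses true vertex identity (available from the
simulator, or supplied as an explicit telomere correspondence).  The
*observed* graph is built from observed adjacencies only: the union's
paths are each closed into a cycle — an even-edge path by one shared
telomeric vertex, an odd-edge path (both end edges in the same genome)
by two fictional vertices and one fictional adjacency of that genome —
and leftover adjacency budget becomes trivial cycles.

One subtlety is not spelled out in textbook descriptions: closing every
path independently needs *f*₁/2 ≥ (number of odd genome-1 paths), which
a small *f* can violate even along a legitimate DCJ history.  The
cycle-maximizing repair is to chain pairs of opposite-genome odd paths
through shared telomeric vertices: each chaining saves exactly one
adjacency per genome and costs exactly one cycle, and no other merge
saves anything.  The implementation performs the minimum number of such
chainings; a randomized test confirms the resulting cycle count equals
the maximum of the real graph over every bijection of non-observed
vertices on small instances.  The parsimony DCJ distance is n − c on
this graph, and observed cycles ≥ real cycles always.

## Sequence coding

Coding each candidate adjacency as a binary site (1 = present) links
the DCJ chain to a two-state symmetric substitution model of length N:
E(D) = (N/2)(1 − (1 − 2/N)^{k_s}).  Half the expected differences
equals E(B_k) exactly for N = 4a(2n−2)/(2n−1) and k_s chosen to match
the decay rates ((1 − 2/N)^{k_s} = (1 − 1/(n−1) − 1/n)^k, i.e.
k_s ≈ 4ka/n); the package verifies this identity to 1e−9 over
k ≤ 4000 at a = 980, n = 1020.  The factor 4 ≈ N/a reflects that a DCJ
changes four sites at once (two adjacencies cut, two formed): a
four-at-a-time substitution model on length N has
E(D4) = (N/2)(1 − (1 − 8/N)^{k_s}).

The sequence-coding estimator inverts E(D) at D = 2B for a chosen N and
converts substitution steps to DCJ steps by the same decay-rate
identification, k = k_s·log(1 − 2/N)/log(1 − 1/(n−1) − 1/n), which
collapses to k̂ = log(1 − 4B/N)/log(1 − 1/(n−1) − 1/n).  This
reproduces the qualitative picture of the length sweep: N = 2n (coding
only observed adjacencies of both genomes) overestimates — and
saturates outright once B ≥ N/4 — while N = n(2n−1) (coding all vertex
pairs) underestimates; N = 4a is near-indistinguishable from the direct
inversion (mean relative difference 0.66% over k ≤ 2n at the published
scale, the (2n−1)/(2n−2) factor being the only discrepancy).

## Random transpositions (EH)

Identifying the n adjacencies with the n elements of a permutation
links breakpoint-graph cycles to permutation cycles under random
transpositions.  The exact series for the transposition walk,

n − Σ_{i≤n} 1/i + Σ_{p=1}^{n−1} Σ_{q=1}^{min(p,n−p)} a_pq
  [(C(p,2) + C(q−1,2) − C(n−p−q+2,2)) / C(n,2)]^k,

with a_pq = (−1)^{n−p−q+1} (p−q+1)² / ((n−q+1)²(n−p)) · C(n−p−1, q−1)
· C(n, p), is implemented verbatim as `eh_formula`.  Exact evaluation
at n = 2 shows the series is the expected transposition *distance*
(0, 1, 0, 1, … while cycles are 2, 1, 2, 1, …), so the cycle
expectation is exposed as n − series; the orientation is pinned by an
exact cycle-type Markov-chain oracle (rational arithmetic, transition
probabilities derived from merge/split combinatorics and cross-checked
against literal enumeration of S_n for n ≤ 5): for all n ≤ 8, k ≤ 20
exactly one orientation matches, and it matches everywhere.

Numerics: a_pq and the bases are computed as exact rationals at any n
(they involve binomials up to ~2^{1.5n}); the k-power sums use mpmath
floats at working precision ≈ 0.46·n + 30 digits, and every evaluation
is repeated at doubled precision — a discrepancy raises a PrecisionError
rather than returning cancelled garbage.  Exact rational power sums are
used only at oracle scale (n ≤ 8), where they are cheap.  Evaluating
the full table for grid inversion costs O(n²k/4) high-precision
operations: seconds at n = 120, minutes at n ≈ 1000 — the known cost of
this estimator.

### What the coupling does and does not guarantee

The simulator can couple a transposition walk to the DCJ run: when a
DCJ cuts the adjacencies mapped to elements ea, eb, the transposition
(ea eb) is applied; after a breakpoint-graph fission the two new
adjacencies are remapped to ea/eb so as to respect the cycles, and
arbitrary choices are resolved smallest-to-smallest.  Since the
adjacency→element map is a history-measurable bijection, the
permutation marginal is an exact uniform transposition walk (its mean
cycle count matches the closed-form series to within Monte-Carlo error,
which validates both the coupling and the series at n = 200).

In expectation the ordering E(BCy_k) ≤ E(Cy_k) holds at every k tested,
with a mean gap growing like k/n.  The *pathwise* ordering
BCy_k ≤ Cy_k, however, is not a theorem of this coupling and fails
empirically at roughly 10% of steps once k exceeds ~n/2 (n = 200,
k ≤ 400): after a fission-nothing event — the DCJ leaves its
breakpoint-graph cycle intact while the transposition necessarily
splits its permutation cycle — one breakpoint-graph cycle holds
elements of two permutation cycles, and a later DCJ within that cycle
can split it (+1) while its transposition merges the two permutation
cycles (−1).  No remapping rule can prevent this: maintaining either
refinement or coarsening between the two cycle partitions is impossible
across fission-nothing events.  The acceptance test states the pathwise
claim and is expected to fail; the expectation-level tests are the
meaningful ones.

## Random graphs (BD)

Identifying adjacencies with vertices of an initially empty n-vertex
multigraph (one uniform random edge over distinct vertex pairs per
step, parallel edges allowed) links breakpoint-graph cycles to
connected components — a coagulation-only caricature of the
coagulation–fragmentation–nothing DCJ process.  The component
expectation is approximated by the tree-count series

(n²/2k) Σ_{i≥1} i^{i−2}/i! · ((2k/n) e^{−2k/n})^i,

whose i = 1 term is n·e^{−2k/n}; that k → 0 limit fixes the prefactor
reading (n²/2k, not n/2k).  The series argument c·e^{−c} never exceeds
1/e, so terms decay; summation stops when a term falls below 1e−12
(cap 10n terms, binding only near c = 1 where terms decay as i^{−5/2}).

The series counts *tree* components only: in the subcritical regime it
telescopes to exactly n − k (Σ i^{i−2}/i!(ce^{−c})^i = c − c²/2 for
c ≤ 1), which sits below the true mean component count by the expected
number of redundant edges (≈ 0.08 at n = 200, k = 50; ≈ 0.8 at k = 100).
That bias is far inside the o(n) accuracy the estimator needs —
|BD − EH| ≤ 0.75√n on n ∈ {50, 100, 200} — but it is systematic, so the
acceptance check demanding the series fall inside a 99% Monte-Carlo
confidence interval at 2000 replicates fails by construction; the test
states that check and is expected to fail.  The Monte-Carlo oracle
itself is an independent union-find implementation.

## Estimation by grid inversion

The cycle-based estimators (EH, BD) have series rather than invertible
closed forms; they estimate k as argmin over integer k ∈ [0, k_max] of
|observed cycles − expected curve(k)|, ties to the smallest k, against
precomputed expectation tables.  The EH curve inverts the observed
breakpoint-graph cycle count against permutation-cycle expectations;
BD matches the same statistic against expected component counts — both
identifications are o(n)-accurate, and self-inversion on noiseless
curves recovers k exactly on the grid.

## Synthetic data and study conditions

All experiments run on genomes from the package's own generator: a
uniformly random matching of the 2g gene extremities leaving a
prescribed number of telomeres, then augmentation.  The published study
conditions state a = 980 observed adjacencies and n = 1020 total; the
accompanying prose gives a genome construction that cannot satisfy
n = 2g − a + f/2 simultaneously, so the package adopts the stated
totals and realizes them as g = 1000 genes, 40 telomeres, f = 0.  The
generator produces uniform random gene orders with the prescribed
telomere count; it does not emulate gene-family content differences,
chromosome-number constraints, rearrangement-rate heterogeneity along
the genome, or hotspots — so passing tests certify the estimators under
the uniform-DCJ model, not robustness to model violation on real
genomes.

The reduced scale used by the test-suite (g = 117, 6 telomeres, f = 0,
so a = 114, n = 120; k_max = 400; 5 replicates) preserves the
telomere-to-gene ratio of the published setup at desk-test cost.  At
this scale the 10%-of-k tolerance for the 5-replicate median estimate
equals the sampling noise itself: across 40 disjoint 5-seed sets the
strict pointwise criterion passes only ~42% of the time (worst-point
relative deviation: median 0.103).  The same claim under the published
conditions (a = 980, n = 1020, 20 replicates) holds with margin —
median within 4.7% for all k ≤ n, and the k-range where the breakpoint
inversion stays within 10% is 2.6× parsimony's — and is tested green at
that scale; the reduced-scale acceptance test keeps its committed seed
and documents the marginality instead of widening the band.

## Numerical and design choices

* Estimator saturation returns a flagged sentinel, never an exception.
* Grid-inversion ties break toward smaller k; hitting the grid end sets
  the saturated flag.
* All randomness flows through numpy Generators; a trajectory's
  breakpoint record is invariant to which optional statistics are
  recorded, and coupled processes consume no extra randomness (the
  rewiring bit decides fission-vs-nothing).
* Observed-cycle recording along a trajectory can be strided
  (`obs_every`) to keep long published-scale runs cheap; unrecorded steps
  are marked −1.
* Exact oracles use rational arithmetic exclusively; probability
  conservation is asserted at every step.
* Degenerate inputs: n < 2 refuses to simulate; an odd f, duplicate
  gene ids, mismatched gene sets, or an insufficient fictional budget
  raise informative errors.

## Known limitations

* Equal gene content only: no duplications, insertions or deletions.
* First moments only: no variances, no confidence intervals for k̂, and
  no tree inference from corrected distances.
* The EH table is expensive at n ≫ 200 (high-precision arithmetic over
  ~n²/4 terms); the breakpoint inversion is the practical estimator at
  chromosome scale.
* Estimates beyond saturation (k ≳ n log n) are unrecoverable in
  principle; the estimators flag rather than extrapolate.
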