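# Methods

## The model

One locus, two alleles *a*/*A*, constant population size *N* of diploid
individuals, discrete non-overlapping generations. A state counts the
genotypes, (n_aa, n_aA, n_AA) with n_aa + n_aA + n_AA = N. Each of the N
offspring of a generation is produced independently:

- **clonally**, with probability *c*: a parent is chosen uniformly and
  copied, each of its two alleles mutating independently with probability
  μ (the 3×3 per-genotype mutation kernel `mutation_kernel(mu)`);
- **sexually**, with probability 1 − c: two gametes are drawn from the
  parental allele pool at allele frequency ν_a = (n_aa + n_aA/2)/N, each
  mutating with probability μ, giving Hardy–Weinberg proportions at the
  mutated frequency ν′ = ν_a(1 − μ) + (1 − ν_a)μ.

A column of the transition matrix is therefore the multinomial
distribution of N independent draws from the single-offspring genotype
distribution π = c·π_clonal + (1 − c)·π_sexual. This kernel is a
reconstruction: it reproduces every structural property the literature
establishes for this model family — density one for μ > 0 (all transitions possible), irreducibility
and aperiodicity, exact partial symmetry under the allele-swap permutation
for symmetric μ, and Hardy–Weinberg convergence at c = 0. Mutation acts on
the clonal pathway too by default; density one for *every* c requires it.
`ModelParams(clonal_mutation=False)` restricts mutation to the sexual
pathway for sensitivity checks, since the literature leaves the order of
cloning and mutation open.

Parameters and defaults: N ≥ 1 (study sizes 5, 20, 100); μ ∈ [0, 0.5] per
allele per generation (reference value 10⁻⁶, a typical per-locus mutation
rate); c ∈ [0, 1] (0 = fully sexual). Multinomial probabilities are
computed in log space with `scipy.special.gammaln`; column sums are exact
to ≲10⁻¹⁴. Entries below ~10⁻³⁰⁸ underflow to exact zeros in double
precision (e.g. the all-*aa* → all-*AA* corner at large N); "density one"
is therefore exact only where the probabilities are representable.

## State ordering and symmetry

States are enumerated lexicographically descending in (n_aa, n_aA):
(N,0,0) first, (0,0,N) last; the ordering is a package convention. `allele_swap_paired_order`
provides a secondary ordering that places allele-swap partners adjacently
to display the partial matrix symmetry. De Finetti coordinates put the
all-*aa* corner at (0,0), all-*AA* at (1,0) and the all-heterozygote apex
at (1/2, √3/2); corner labels can be changed by permuting the state counts
before plotting.

## Sparse approximation

Per column i (0-based), with threshold s: (1) rank entries by decreasing
value, ties by ascending row index (stable sort); (2) find the minimal
rank whose cumulative sum reaches s; (3) raise it to at least 2; (4)
extend it across ties; (5) zero everything beyond, except rows
{(i−1, i, i+1) mod |S|} — protected rows are kept only if nonzero in the
original, entries are never created; (6) rescale the column to one.  The
wrap-around protected diagonals form a Hamiltonian cycle through all
states, which guarantees irreducibility even though the wrapped neighbors
are not biologically adjacent; the retained diagonal guarantees
aperiodicity.

Accounting: the discarded (pre-rescale) mass per column is ≤ 1 − s, so the
total L1 perturbation before rescaling is ≤ (1 − s)·|S|; after rescaling
each column moves by at most 2(1 − s). Both sides are asserted in tests
because the bound is meaningful on either side of the rescaling. Density is counted as stored nonzeros over |S|².

## Spectral computations

The limiting distribution is computed with implicitly restarted Arnoldi
(`scipy.sparse.linalg.eigs`, k = 1, largest magnitude) on the same code
path for dense and sparse storage, then validated: eigenvalue within 10⁻⁶
of 1, real non-negative entries, residual ‖Mv − v‖₁ < 10⁻⁸. Plain power
iteration (convergence when the successive L1 change < 10⁻¹³ or the
residual < 10⁻¹⁰, cap 10⁶ iterations) and a full dense solve are available
as alternatives and agree to ~10⁻⁹. A reducible chain (μ = 0, c < 1, with
absorbing fixation states) has a non-simple eigenvalue 1; the validation
then either refuses or returns a vector supported on the fixation states —
both outcomes are acceptable and documented behavior.

First-passage times solve t(I − M′) = 1 (column convention, M′ the
non-target sub-matrix) with a direct dense or sparse LU solve; target
entries are zero, non-positive or non-finite solutions raise (unreachable
targets).

## Network analytics

Edges are j → i with weight M[i, j]; zero entries (possible after
approximation) are absent edges, not infinite costs. Most probable paths
use Dijkstra on costs −log M[i, j] (`scipy.sparse.csgraph`); among tied
optima the lexicographically smallest state sequence is chosen, via a
greedy walk over the shortest-path DAG with tolerance 10⁻⁹·(1 + cost).
Betweenness counts, for every ordered pair, the interior nodes of that
single tie-broken path — integer counts, not fractional shares, so the
statistic is exactly reproducible. Self-loops are excluded from paths;
the most-probable-neighbor display offers both including and excluding the
self-loop, since near-absorbing states are their own most likely
destination.

## F_IS distributions and divergences

F_IS = 1 − ν_aA/(2 ν_a ν_A) is kept as an exact rational per state
(`fractions.Fraction`), so states sharing a value aggregate exactly;
binning is left to display code. Monomorphic states (ν_a ν_A = 0) have no
F_IS; their long-run mass is tracked as `undefined_mass` and omitted from
all comparisons. Divergences between two equilibrium F_IS distributions
(total distance, Kullback–Leibler, Cressie–Read power divergence with
λ = 2/3, Kolmogorov–Smirnov) are computed over the union of defined
classes on the **raw** class masses, without renormalizing over the
polymorphic states: this is the convention under which "total distance"
between original and approximate distributions is small when the
eigenvectors are close, and it keeps the omission of undefined/infinite
terms symmetric with the G-test. `conditional=True` renormalizes first;
note that at small μ the polymorphic mass is ~10⁻³, so conditional
distances magnify the approximation error by orders of magnitude (the
approximation systematically concentrates conditional mass toward the
near-fixation classes by pruning transitions into deeper polymorphism).
KL and power-divergence terms with a zero denominator are omitted; the
G-test reports how many classes it dropped, uses a pseudo-count scale
n_eff (default 1000 — the comparison is qualitative and n_eff has no
canonical value) and a χ² reference with (retained − 1) degrees of
freedom.

## Morris screening

Grids: N ∈ {10, …, 100} step 10; μ ∈ {10⁻¹², …, 10⁻³} by decade (the
normalized coordinate is the grid index, i.e. uniform on the exponent);
c ∈ {0.1, …, 1.0} step 0.1; s ∈ {0.80, …, 0.98} step 0.02. The default of
r = 30 trajectories × (k + 1) = 5 points gives 150 model evaluations
(r = 150 trajectories is available by configuration).
Each trajectory starts at a random grid point and moves each parameter
once, in random order, by exactly one grid step (reflected at the
boundary); elementary effects are (Δy)/(Δx) in normalized coordinates, so
a linear output recovers its coefficients exactly (μ* = |a|, σ = 0).
Non-finite outputs and failed evaluations void only the effects they
touch. Per evaluation point the pipeline records the sparse density and
all divergence statistics between the original and approximate equilibrium
F_IS distributions.

The test suite's screening run is scaled down (N ≤ 30, r = 5, 25
evaluations) — chosen so the whole suite stays interactive while still
exercising every stage; `scripts/acceptance.py` runs the full 150-point
design (a few minutes on one CPU).

## What the fixtures emulate

Toy 3×3/5×5 chains and seeded random strictly positive matrices stand in
for generic ergodic chains in oracle tests (brute-force path enumeration,
Monte-Carlo hitting times); model matrices at N ∈ {5, 20, 100} are the
study systems themselves, generated from the kernel at run time. No
external data exist in this problem; consequently the tests validate
mathematical structure and cross-implementation agreement, not fit to
empirical genotype data — conclusions about real populations inherit all
the model's assumptions (constant N, symmetric single-locus mutation,
independence of offspring, time-homogeneity).

## Numerical choices and degenerate inputs

- Column sums validated on read: warn above 10⁻⁶ deviation, fail above
  10⁻³; freshly built matrices are exact to ~10⁻¹⁴.
- Approximation requires columns normalized to 10⁻⁹ and s ∈ [0, 1]; a
  column where nothing is dropped is returned bit-identical (no rescale).
- Ties in step 4 are exact float equality; ranking ties break by
  ascending row index (stable sort).
- Dense materialization refuses beyond 8000 states by default
  (|S|² doubles ≈ 0.5 GB) and reports the computed |S|; the streaming
  column generator plus `approximate_matrix` handle larger systems with
  peak memory of one column plus the sparse result.
- Transforms keep ±inf sentinels; TSV exports write them literally.

## Known limitations

- The transition kernel is a reconstruction (see above); absolute
  quantities that depend on fine kernel details (e.g. the exact
  equilibrium mass of rare classes) may differ from other implementations
  of the same model family.
- The qualitative claim that the s = 0.9 approximation error on the
  equilibrium F_IS distribution stays below the c = 0 vs c = 0.1 contrast
  at N = 100, μ = 10⁻⁶ does **not** hold here under any comparison
  convention we examined (raw, conditional, or binned classes): at this
  mutation rate the equilibrium is fixation-dominated and a 10% clonality
  rate changes it only at the 10⁻⁵ level, below the s = 0.9 approximation
  error (~1.5·10⁻³). The corresponding acceptance test documents this
  honestly and fails.
- Lumping-based exact reduction, external-memory paging, multi-locus or
  polyploid state enumeration (only their cardinalities), selection,
  migration and asymmetric mutation are out of scope.
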