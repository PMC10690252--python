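# Methods

## Null model

An annotation of a chromosome of length L is a set of half-open integer
intervals in [0, L), pairwise separated by at least one uncovered base, or
equivalently a binary sequence Q₀ … Q_{L−1}. A *genome context* is a map
ϕ: {0, …, L−1} → Λ from positions to a finite set of class labels, stored
run-length encoded; c denotes the number of class boundaries (positions
whose label differs from their predecessor).

The generative model is a two-state Markov chain with one 2×2 transition
matrix T(λ) per class: states S₋₁, S₀, …, S_{L−1} are drawn with

Pr[(S₋₁, …, S_{L−1}) = (s₋₁, …, s_{L−1})] = π_{s₋₁} · ∏ᵢ T(ϕ(i))_{s_{i−1}, s_i},

where π is the stationary vector of T(ϕ(0)),
π = (T₁₀/(1 − T₀₀ + T₁₀), (1 − T₀₀)/(1 − T₀₀ + T₁₀)). The covered
positions (state 1) induce the annotation. With a single class this is the
classic geometric interval/gap model; multiple classes let interval density
and length scale differ between, say, gap, GC or repeat strata, and
intervals may freely span class boundaries.

The null hypothesis for a query Q under context ϕ is that Q was generated
by the chain whose matrices are fitted from Q itself: for each class λ the
four transition-pair counts

c_{λ,s,s'} = 1 + Σ_{i=1}^{L−1} 1(ϕ(i) = λ and Q_{i−1} = s and Q_i = s')

are accumulated (pooled over chromosomes) and row-normalized. The
pseudocount 1 keeps all probabilities strictly positive. The pair at
position i is attributed to the class of the *destination* position i,
following the count formula literally; the transition from S₋₁ to S₀ is not
counted. Training is O(|Q| + c) by run-length arithmetic (interval starts,
ends and interior coverage are counted per context segment with sorted
searches and prefix sums — no per-position pass).

## Exact moments via two-sided plumbuses

K(R, Q) (reference intervals overlapping Q) and B(R, Q) (jointly covered
bases) are *separable*: sums over reference intervals of contributions
v(S_i, …, S_{j−1}) local to each interval [i, j). The engine computes exact
E and Var of the total under the null.

For a piece [i, j) of the chromosome the *two-sided plumbus* stores, for
each boundary state pair (x, y) ∈ {0,1}²:

* μ(x, y) = E[v | S_{i−1} = x, S_{j−1} = y],
* σ²(x, y) = Var[v | S_{i−1} = x, S_{j−1} = y],
* Ψ(x→y) = Pr[S_{j−1} = y | S_{i−1} = x].

Adjacent plumbuses merge by summing out the shared boundary state m: Ψ
composes as a matrix product; with weights
w_m = Ψ_L(x→m) Ψ_R(m→y) / Ψ(x→y), means add (μ = Σ w_m (μ_L + μ_R)) and
variances follow the law of total variance
(σ² = Σ w_m (σ²_L + σ²_R) + Σ w_m (μ_L + μ_R)² − μ²). The merge is
associative; the engine folds strictly left to right across the alternating
gap/interval layout of the chromosome, then removes the conditioning with
the joint boundary weights p_{x,y} = π_x Ψ(x→y). Cells with Ψ = 0 are
unreachable: they carry sentinel zeros and receive zero weight downstream,
which avoids 0/0 without branching the algebra.

Building-block plumbuses:

* **gap**: μ ≡ σ² ≡ 0; Ψ is the product of n-step matrices over the gap's
  same-class runs. The n-step matrix is the O(1) closed form
  Tⁿ = Π + (1 − a − b)ⁿ (I − Π) with a = T₀₁, b = T₁₀ and Π the stationary
  projector.
* **K interval**: the contribution is an overlap indicator. With
  z(x) = Pr[all states 0 | x] (a product of T_{x,0} T₀₀^{n−1} factors over
  runs), μ(x, 0) = 1 − z(x)/Ψ(x→0) and σ² = μ(1 − μ); y = 1 forces μ = 1.
* **B interval**: equivalent to folding single-position plumbuses
  (μ(x, y) = y, Ψ = T). Within a same-class run the result depends only on
  the run length, so a per-class *doubling ladder* of power-of-two
  plumbuses is cached and combined along the binary representation of the
  run length — O(log t) merges per run.

Total cost: O(|R| + c) plumbus merges for K and O((|R| + c) log t) for B
(t = longest same-class stretch inside a reference interval, measured, not
capped); space O(|R| + c). Chromosomes are independent under the model, so
genome-level mean and variance are sums of per-chromosome values, and
chromosomes may be processed in parallel with a deterministic sorted-name
merge.

Z = (A − E)/√Var converts to p-values 1 − Φ(Z) (enrichment) and Φ(Z)
(depletion); log₁₀ p is computed from the normal log-tail so extreme Z
report meaningful magnitudes after the linear value underflows.

## Exact PMF mode

A dynamic program sweeps each chromosome carrying the joint distribution of
(state at the current boundary, statistic so far): gaps update the state
marginal through the same n-step products; a K interval branches into
(y = 1, +1), (y = 0, +1) with probability Ψ(x→0) − z(x), and (y = 0, +0)
with probability z(x); B intervals step base by base. Per-chromosome PMFs
are convolved directly (no FFT needed at the guarded sizes). Cost is
quadratic — in |R| for K (a warning fires above 5·10⁴ intervals per
chromosome) and in the total reference length for B (hard guard at 10⁴
bases, erroring with a pointer to the moments mode). Exact-mode p-values
are tail sums including the observed value (Pr[A' ≥ A] for enrichment).

The exact mode matters for small references: the acceptance suite checks
that at |R| = 200 the exact right tail exceeds the normal approximation at
the first integer threshold with Z ≥ 3 in ≥ 90% of instances, so normal
p-values there understate the tail and the exact mode is recommended
(the library warns below 500 reference intervals; configurable).

A brute-force enumerator over all 2^(L+1) state sequences (L ≤ 16) is part
of the public API and serves as the independent ground truth for both the
moment engine and the DP in the test suite — three routes, one answer.

## Sampling

`sample()` draws annotations from a chain by geometric sojourns: given the
previous state s, the number of further positions keeping state s is
geometric with parameter 1 − T_{ss}, so whole runs are drawn at once.
Truncation at a class boundary is exact by memorylessness, and the next
run is redrawn under the new class matrix (which changes the sojourn
parameter anyway). This is distributionally identical to the per-position
chain but costs O(number of state switches), which makes the 10⁷-bp
recovery check and the 2 000-replicate bootstrap cheap. S₋₁ comes from the
stationary vector of the first segment's class; a fixed seed gives a
byte-identical annotation.

## Synthetic data

`synth_annotation` places n fixed-length intervals uniformly at random
among all configurations with ≥ 1-base separation, via order statistics:
sorted uniform draws u₁ ≤ … ≤ u_n on [0, L − n(ℓ+1)] plus offsets
k(ℓ+1) form a bijection onto valid start tuples, so the draw is exactly
uniform with no rejection loop and deterministic by seed. Defaults
(L = 10⁶, 500 intervals of 500 bp) are a 1/100-scale version of the
standard large-genome benchmark layout (10⁸ bp, 50 000 query intervals);
reference sizes in the acceptance suite sweep 200–20 000 intervals at the
same interval length. What the generator does *not* emulate: clustering of
real annotations, length heterogeneity, chromosome-to-chromosome density
differences, and correlation between annotations — so passing calibration
tests show correctness of the null computation, not that the Markov null is
an adequate model for any particular real annotation pair.

Test problem sizes were chosen so the whole suite and the acceptance script
each run in well under a minute of CPU: enumeration cross-checks use
L ≤ 14 (here the 2^(L+1)-sequence oracle is exact), medium-scale
consistency uses L = 10⁵ with |R| = 300, calibration uses 2 000 bootstrap
replicates at L = 10⁵, and the complexity sweep uses L = 2·10⁷ with |R| up
to 20 000.

## Numerical conventions and edge cases

* All probability arithmetic is in linear space with doubles; two-state
  chains are well-conditioned. |1 − a − b| is clamped to ≤ 1 before
  powering.
* Variances are clamped at 0 from below after each merge; a plumbus whose
  Ψ rows deviate from stochasticity by > 10⁻⁸ aborts with a
  numerical-health error.
* Degenerate stationary denominator (T₀₀ = 1, T₁₀ = 0) returns (1, 0); it
  cannot arise from training with pseudocounts, only from user-supplied
  matrices.
* An empty reference gives mean 0, variance 0 and a "degenerate" result
  status with p-values omitted (NaN) rather than guessed; zero-variance
  results never fabricate a Z.
* Overlapping or bookended BED records are merged on input (the only
  lossless normalization consistent with the ≥ 1-base separation
  invariant); records with begin ≥ end or outside [0, L) are hard errors
  naming the offending line; records on chromosomes absent from
  chrom.sizes are dropped with a warning.
* Context BED: uncovered positions get a caller-named default label
  (default `background`), so running without a context file is identical
  to a single-class whole-genome context. Same-label overlaps merge;
  conflicting-label overlaps are errors.
* GC contexts: fixed windows (default 1 kbp), a window ≥ 50% N becomes the
  gap class, otherwise equal-width right-closed GC bins on [0, 1]
  ((k/n, (k+1)/n], GC = 0 in bin 0) with N bases excluded from the
  denominator. Window-level N handling and bin edges are this package's
  stated choices; other discretizations are defensible.
* Strand is ignored everywhere; the model is strand-free.

## Design choices

* The fold over a chromosome is strictly left-to-right rather than a
  balanced tree: same asymptotics, simpler, and merge order is irrelevant
  by associativity.
* Multiple-testing correction is not built into the statistics; the CLI can
  append Benjamini–Hochberg q-values over the genome rows of a batch run as
  an explicitly labelled convenience (`--bh`, off by default), since the
  method itself reports raw per-pair p-values.
* Per-chromosome parallelism only (`--threads`), with results merged in
  sorted chromosome order — output is byte-identical to a serial run. No
  intra-chromosome parallelism.
* Stochastic subcommands require an explicit `--seed`; there is no silent
  time-based seeding.
* The exact mode uses the stationary-at-position-(−1) initial convention
  throughout, matching the generative definition (not the older
  always-start-in-state-0 convention some tools use).

## Limitations

* The normal approximation degrades in the extreme tail for small |R|; use
  the exact mode there (the package warns).
* Contexts are categorical; quantitative covariates (raw GC, conservation
  scores) must be discretized by the user.
* Only K and B ship; the plumbus engine is written against a generic
  separable contribution and keeps that seam, but no user-pluggable
  statistic is exposed in the CLI.
* The exact-B dynamic program is quadratic in reference length and guarded
  accordingly; it is a verification tool and a small-reference fallback,
  not a large-scale path.
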