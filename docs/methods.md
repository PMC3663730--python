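# Methods

## Model

A symmetric nonnegative adjacency matrix `A` over `n` nodes (diagonal
ignored everywhere) is approximated by

    A_ij ≈ mu_ij = r[c_i, c_j] * p_i * p_j,   i ≠ j,

where `c` assigns each node to one of `K` non-empty proper clusters (label 0
is reserved for improper nodes left out by the initial cut), `p ≥ 0` are
per-node propensities, and `R` is a symmetric cluster similarity matrix with
a fixed unit diagonal.  Fixing `r_aa = 1` removes the scale indeterminacy
between `p` and `R`: within a cluster the model is the conformity
factorization `A_ij ≈ p_i p_j`, so propensities are uniquely determined (for
`n ≥ 3` nodes with positive adjacencies), and `r_ab` is interpretable as an
adjacency between clusters.

Two objectives are implemented, both summed over ordered pairs `(i, j)`,
`i ≠ j`, so each unordered pair contributes twice; this doubled scale is
used consistently by the updates, the stationarity checks and AIC/BIC.

* **Poisson** branch (edge counts, possibly non-integer): maximize
  `sum A_ij*ln(mu_ij) - mu_ij - lnGamma(A_ij + 1)`, with `0*ln 0 = 0` and a
  `-inf` return (not an exception) when a positive count meets a zero mean.
  `K = 1` is the pure propensity Poisson (PPP) model.
* **Frobenius** branch (weighted similarities in `[0, 1]`): minimize
  `sum (A_ij - mu_ij)^2`.

Estimated `r_ab` are expected in `[0, 1]` for genuinely modular data but are
not constrained; values above 1 trigger a warning only.  Directed networks
and negative similarities are out of scope.

## Estimation

For a fixed assignment, estimation alternates two blocks until the
objective changes by less than `tol` (default `1e-5`):

1. **Similarity update (exact).**  Setting the partial derivative in each
   `r_ab` to zero gives closed forms: total inter-cluster count over the
   product of cluster propensity sums (Poisson), or the `p`-weighted
   inter-cluster adjacency sum over the product of squared-propensity sums
   (Frobenius).  A cluster pair with no connecting weight gets `r_ab = 0`;
   edges into a cluster with zero total propensity are unidentifiable and
   raise.
2. **Propensity update (MM).**  The arithmetic–geometric mean inequality
   (plus `x ≥ 1 + ln x` in the Frobenius case) yields a surrogate with
   separated parameters, giving the simultaneous updates

       Poisson:    p+_i = sqrt( p_i * k_i / sum_{j≠i} r[c_i,c_j] p_j )
       Frobenius:  p+_i = [ p_i^3 * sum_{j≠i} r A_ij p_j
                            / sum_{j≠i} r^2 p_j^2 ]^(1/4)

   with `k_i` the node's connectivity.  Each step moves the objective
   monotonically in the correct direction; a node with no incident weight
   maps to `p_i = 0` and is excluded from denominators thereafter.  The
   square-root and fourth-root exponents follow from the surrogate
   derivations (the surrogate's stationary condition is solved for
   `p_i^2` resp. `p_i^4`).

Propensities are initialized as connectivity over the square root of total
connectivity — exact for a single cluster when `sum p` dominates
`sum p^2` — and `R` is initialized by its own closed-form update.  The inner
propensity loop runs to a relative-change tolerance `max(tol, 1e-7)`
(at most 500 iterations) between similarity updates.

### Quasi-Newton acceleration

MM iterations converge linearly and stall near the optimum.  The inner loop
therefore keeps a FIFO buffer of up to `q = 6` secant pairs
`u = F(x) - x`, `v = F(F(x)) - F(x)` of the MM map `F` and proposes the
extrapolation

    x+ = F(x) - V (U'U - U'V)^{-1} U' (x - F(x)),

which approximates a Newton step for the fixed-point equation `x = F(x)`
using a low-rank secant model of `dF`, at the cost of one small `q x q`
solve.  A proposal is accepted only if it keeps every propensity
nonnegative and beats the two plain MM steps already computed for the
secant; otherwise it is discarded along with the oldest secant and the MM
step is taken.  The safeguard makes the recorded objective trace exactly
monotone, and accelerated and unaccelerated runs converge to the same
optimum (verified to `1e-6` in the tests).  Acceleration is applied to the
inner propensity iterations only: the outer similarity update is an exact
closed form, so outer cycles are few and extrapolating the concatenated
`(p, R)` vector would complicate the monotonicity guarantee for little gain.
The buffer is cleared whenever the assignment changes, since the parameter
meaning changes with it.

## Cluster search

The full fit alternates parameter estimation (above) with greedy node
reassignment, with all parameters held fixed during reassignment — the two
phases are individually monotone, so the whole trace is.  Reassignment
visits nodes in a seeded random permutation; for each node the objective
contribution of its row is evaluated under membership in every proper
cluster (only terms touching the node change), and the node moves on strict
improvement greater than `1e-12` (ties keep the current cluster; a move
that would empty a proper cluster is skipped).  Passes repeat until one
makes no move; estimation/reassignment cycles repeat until the assignment
is stable or `max_cycles` (default 50) is hit, in which case the best model
so far is returned with `converged = False`.

Initial clusters come from average-linkage hierarchical clustering of the
dissimilarity `1 - A/max(A)`, cut either to a requested `K` or at 99% of the
highest merge height; clusters smaller than `min_cluster_size` (default 3)
are sent to the improper label 0.  Label-0 nodes keep propensities, get a
similarity row estimated like any pseudo-cluster, and may be pulled into
proper clusters during reassignment; nodes never enter label 0.  Random and
user-supplied initializations are also available; on well-separated data
different initializations reach the same final model (tested).

### Number of clusters

For the Poisson branch, `select_n_clusters` fits each candidate `K` and
reports `AIC = -2 lnL + 2c` and `BIC = -2 lnL + c ln(N)` with
`c = n + K(K-1)/2` free continuous parameters (hard labels are treated as a
model-structure choice, not counted) and `N = n(n-1)` ordered pair terms as
the sample size, matching the objective's scale.  Both conventions are
documented choices rather than settled theory, and every report carries the
caveat that AIC/BIC invoke regularity assumptions that latent cluster
labels violate; in our own simulations the criteria overfit mild structure
by splitting off small extreme subclusters and only agree on the generating
`K` when the structure is strong (see the test suite).

## Edge significance

Conditioned on the fitted parameters (no refitting excluding the tested
pair), the count between two nodes is Poisson with mean `mu_ij`.  A pair is
scored by the inclusive upper tail `P(X ≥ n_obs)`; the deficit (lower) tail
is available behind a flag but unused by default.  `observed = 0` gives
`p = 1`; a positive count with zero mean gives `p = 0`.  Output tables are
ranked by `-log10(P)` (capped at 300), flag intra- versus inter-cluster
pairs, and report counts below 0.01 and 0.001.  No multiple-testing
correction is applied by default, matching how raw thresholds are usually
reported for this test; Benjamini–Hochberg adjustment is optional.  Because
PPP has no cluster term, dense intra-cluster pairs all look like excesses
under it: PPP p-values for intra-cluster pairs sit at or below the
cluster-aware model's, while genuine cross-cluster excesses are flagged
more sharply by the cluster-aware model (both directions tested).

## Synthetic designs

All generators are seed-deterministic and return their ground truth.

* **Planar clusters** — four Gaussian clusters (identity covariance) of
  sizes 50/100/150/200 at centers (0,0), (8,0), (0,12), (12,10);
  adjacency `1 - (d/max d)^2`.  The centers were chosen so that all six
  pairwise distances are distinct (a tie would make the rank-correlation
  property fragile) and separations are large relative to the unit scatter,
  so the generating clusters are unambiguous and exactly recoverable.
  Under this design the fitted inter-cluster similarities decrease
  monotonically in the distance between cluster sample centers (Spearman
  correlation −1; `scripts/acceptance.py` recomputes this), and within each
  cluster propensity tracks connectivity and falls with distance from the
  network's overall center of mass.  Note the within-cluster connectivity
  decomposition involves the mean over *all* points, so the distance to the
  node's *own* cluster center is only weakly informative once clusters are
  far apart.
* **Block multigraph** — 0/1 block-diagonal matrix (default blocks
  100/200/500) with 20 off-block entries per block pair switched to 1
  (60 planted pairs).  Used for the significance comparison: the
  cluster-aware model flags every planted pair at `p < 0.01` and assigns
  each a strictly smaller p-value than PPP; scoring off-block pairs by
  `-log10(P)` (positives = planted, negatives = other off-block pairs)
  gives AUC ≈ 1.  This scoring construction is one reasonable choice among
  several; reported AUCs under other constructions are treated as
  directional only.
* **Factorizable networks** — `A = f f^T` off-diagonal; the Frobenius fit
  with `K = 1` recovers `f` exactly (objective < 1e-10, relative error
  < 1e-6 at `tol = 1e-13`).
* **Poisson multigraphs** — counts drawn from a known `(c, p, R)`;
  with separation (`r_ab ≤ 0.2`, within-cluster means ≥ 3, n = 200) the fit
  recovers clusters exactly, propensities within 10% RMS and similarities
  within 15%.
* **Co-expression emulation** — `K = 5` latent eigengene profiles over 120
  samples with a prescribed correlation matrix (drawn from bounded random
  two-factor loadings, off-diagonal magnitudes ≲ 0.5; profiles are
  orthogonalized before mixing so empirical correlations equal the design
  exactly); node `i` in module `a` is `kME_i * u_a + sqrt(1-kME_i^2) *
  noise` with `kME ~ U(0.6, 0.98)`, and the adjacency is `|corr|^beta`,
  `beta = 6` (the customary soft-thresholding power).  The fitted
  propensities track `kME^beta` within modules (r > 0.9) and the fitted
  `r_ab` track `|corr(u_a, u_b)|^beta` (r > 0.8).  This generator emulates
  the modular structure of co-expression data, not its full complexity: no
  unassigned background genes, no negative-correlation modules, no
  heteroscedastic noise — so passing tests show the decomposition recovers
  the latent structure it models, not that it handles every artifact of
  real expression data.

Problem sizes in the test suite (n up to 800, 100 random instances for the
update-correctness checks) keep the default run around half a minute while
exercising every code path at the study designs' stated shapes.

## Numerical choices and limitations

* `ln(A_ij!)` is always `lnGamma(A_ij + 1)`; integer and non-integer counts
  share one code path.
* Input symmetry: deviations up to `1e-8` are averaged away (with a warning
  when read from disk); larger ones are hard errors.
* Reassignment tie-break keeps the current cluster; the `1e-12` improvement
  threshold prevents cycling on float noise.  Identical inputs and seed
  give byte-identical outputs.
* The search is greedy block-coordinate: it guarantees monotone improvement,
  not a global optimum.  Poor initializations on weakly structured data can
  end in local optima; hierarchical initialization is the practical default.
* Very large networks (10^4+ nodes) would need block pre-clustering before
  the per-node reassignment sweep; that divide-and-conquer layer is not
  implemented here.
* Significance tests condition on the global fit and ignore the uncertainty
  of the estimated parameters; with many tested pairs, use the optional
  Benjamini–Hochberg adjustment.
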