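# Methods

## Scope and data model

Everything operates on a `BinaryDataset`: an n × p matrix over {0, 1}
with unique item labels, no missing values (exclusion happens upstream,
in `cohort.dichotomize_change_items`, which counts dropped rows). The
canonical cohort is 12 sleep/mental change items — WT, BT, Sleep
quantity, Mental fatigue, Irritability, SOL, Sleepiness, Physical
fatigue, Sleep quality, Satisfaction, WASO, Attention — where 1 means
"changed" and 0 means "no change, or change in the opposite direction";
the instrument cannot distinguish the latter two, and neither do we.

## Synthetic cohorts

The estimation method assumes a pairwise binary Markov random field, so
that is the generative family used for ground truth: the {0,1}-domain
Ising model P(x) ∝ exp(τ·x + ½ xᵀWx). Three generators:

* **Exact enumeration** (`enumerate_ising_distribution`): all 2^p
  states, p ≤ 16 enforced. This is the oracle every sampler is tested
  against; probabilities sum to 1 to 1e-12.
* **Gibbs sampler**: single-site sweeps with the full conditional
  P(xᵢ=1|rest) = logistic(τᵢ + Σⱼ Wᵢⱼxⱼ). Defaults burn_in = 1000
  sweeps, thin = 10 — deliberately conservative for the weak-coupling
  p = 12 regime, so rows are effectively independent draws. All
  randomness flows through explicit integer seeds (numba's RNG for the
  sampler, `numpy.random.default_rng` elsewhere); identical seeds give
  bit-identical output.
* **Bayesian-network forward sampler** for DAG-recovery tests: nodes in
  topological order from their CPTs.

The **study-like cohort** (n = 414 by default) fixes the marginal
endorsement probabilities at the published values (0.87, 0.85, 0.78,
0.57, 0.53, 0.50, 0.50, 0.44, 0.43, 0.38, 0.23, 0.18) and plants the
six strongest reported pairwise dependencies as couplings with the
reported magnitudes: +2.43 (Sleep quality–Satisfaction), +2.42 (Sleep
quantity–WT), +1.86 (Physical fatigue–Sleepiness), +1.79 (Mental
fatigue–Irritability), −1.27 (Irritability–Attention), −1.26 (WT–WASO).
Thresholds are calibrated so the *exact* (enumerated) marginals hit the
targets, via `scipy.optimize.root` on the 12-dimensional system; with
p = 12 the state space (4096) is enumerable, which makes calibration
deterministic with no Monte Carlo error. The pairwise odds ratios of
the real data were never published, so the cohort targets marginals and
edge signs/magnitude ordering, not the full dependence structure; a
green recovery test establishes that the estimator finds what was
planted, not that the generator reproduces the real cohort's joint
distribution. No ordinal structure, missingness, or longitudinal
dependence is simulated.

## Ising estimation (eLasso)

Node-wise ℓ1-penalized logistic regression with EBIC selection:

* λ path: 100 log-spaced values from λ_max = max|Xᵀ(y−ȳ)|/n (the
  smallest λ that zeroes every coefficient) down to 0.001·λ_max,
  warm-started downward.
* Solver: IRLS with an inner coordinate descent on the weighted
  least-squares approximation, using precomputed sufficient statistics
  (XᵀWX, XᵀWz) so inner sweeps cost O(p²); outer convergence when the
  largest coefficient change falls below 1e-7. The intercept is never
  penalized; predictors stay on their raw {0,1} scale, so coefficients
  are log-odds interactions. Coefficients within 1e-6 of zero after
  convergence are treated as exact zeros — round-off at the
  soft-threshold boundary can otherwise leave ~1e-16 coefficients on
  the path, which would make the null model invisible to EBIC.
* Selection: EBIC_γ = −2ℓ + k ln n + 2γ k ln(p−1), γ = 0.25 by default
  (the eLasso ecosystem convention). Ties go to the sparser model
  (larger λ; argmin over a decreasing path does this).
* Symmetrization: AND rule by default (edge kept only when both
  directed regressions keep it; weight = mean of the two); OR rule
  available (kept when either does; weight = mean of the nonzero
  estimates).

Expected influence is the signed row sum of the weight matrix;
z-scores standardize across nodes with the sample SD (ddof = 1).
Printed EI values are z-scores.

## Stability

* **Edge bootstrap**: resample n rows with replacement, re-estimate
  with identical settings, 95% CIs from the 2.5/97.5 empirical
  quantiles. Replicates with a constant column are redrawn and counted.
* **Difference test**: significant iff the 95% empirical CI of the
  paired replicate differences excludes 0; symmetric by construction.
* **Case dropping**: default grid 0.05, 0.10, …, 0.75; at each drop
  fraction q, subsamples of ⌈(1−q)n⌉ rows without replacement are
  re-estimated and the statistic vector (per-node EI, or vectorized
  upper-triangle weights) is Pearson-correlated with the full-sample
  vector. Degenerate subsamples (constant column or constant statistic)
  yield NaN, which counts as a failed replicate rather than being
  dropped; grid points whose retained size falls below 20 rows are
  flagged unavailable.
* **CS-coefficient**: the largest q whose fraction of replicates with
  r ≥ 0.7 is ≥ 0.95, *required to hold at every smaller grid point as
  well*. The monotonicity clause is imposed so CS is well defined when
  stability is non-monotone in q; without it a lucky large-q point
  could report spuriously high stability. Reports carry the
  interpretation bands (ideally > 0.5; not below 0.25). CS resolution
  equals the grid resolution (0.05 by default); finer published values
  imply a finer grid, which the API exposes.

## Directed networks

* **Score**: BIC = ℓ − (ln n/2)·k with k = Σ_nodes 2^|parents|, higher
  better, multinomial log-likelihood at the empirical conditional
  frequencies (0·log 0 = 0). With this sign convention the per-arc BIC
  strength — BIC(without arc) − BIC(with arc) — is *negative* for
  structurally important arcs, which matches how the published values
  are printed; the opposite "higher is more important" phrasing that
  sometimes accompanies such tables is inconsistent with those values
  and is not followed.
* **Search**: greedy hill-climbing from the empty graph over single-arc
  additions, deletions and reversals that preserve acyclicity, taking
  the largest positive gain; decomposable scoring re-scores only
  affected children, with a cache. Ties break lexicographically by
  (add < delete < reverse, parent label, child label), making the
  search deterministic given the data. No restarts, tabu list, or
  parent-set cap — at n ≈ 414, p = 12 the search space is benign.
* **Bootstrap averaging**: m replicates (10,000 by default; tests and
  the acceptance script use 200–1000 to stay within time budgets —
  strengths are binomial proportions, so at m = 1000 their SE is
  ≤ 0.016), resampling n rows with replacement. Strength = fraction of
  replicates with an arc between the pair in either direction;
  directional probability = fraction of those pointing a given way
  (the two orientations sum to 1).
* **Significance threshold**: the Scutari–Nagarajan estimator — the
  noise/significant split of the observed strengths whose ideal
  two-point CDF (mass at 0 and 1) is closest in L1 to the empirical
  CDF; the threshold is the midpoint between the two groups. A fixed
  cutoff (e.g. 0.5) can be passed instead. If all strengths are equal
  the threshold is set just below them (everything significant).
* **Averaged network**: retained pairs are oriented by majority
  direction; arcs with directional probability below 0.51 are flagged
  as bidirectional tendencies but still drawn. If majority orientations
  ever induce a cycle, the arc with directional probability closest to
  0.5 is reversed (repeatedly, logged in `cycle_reversals`); this is a
  minimal intervention and did not trigger on any tested cohort.

## ISI scoring

Seven items, each 0–4; total 0–28. Categories: 0–7 none, 8–14
subthreshold, 15–21 moderate, 22–28 severe; ≥ 15 is the clinically
significant cutoff used for prevalence. The 8/14/21 band edges are the
instrument's standard convention rather than something the change-item
analysis needs; they exist so "moderate to severe" prevalence is
computable.

## Known limitations

* Recovery guarantees are for the planted-truth synthetic world; on
  real data the Ising and DAG stages share all the usual caveats of
  regularized network estimation (AND-rule conservatism at small n,
  greedy search local optima, bootstrap undercoverage for shrunken
  edges).
* At n = 414 the weaker planted couplings (|W| ≈ 1.3) are sometimes
  missed by the AND rule; full sign recovery is only asserted at
  n = 2000.
* Finite-sample fluctuations can put a genuinely-supported extra arc
  into the averaged DAG (observed once in ten seeds for a 3-node chain
  at n = 1000 — the offending dataset really does carry a conditional
  dependence with G² ≈ 17); this is a property of BIC-based averaging,
  not of the implementation.
* The chronotype label is carried as an opaque categorical; no scoring
  logic is attached to it.
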