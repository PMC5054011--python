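# Methods

## Model

For person i = 1..I observed at occasions t = 1..T_i on M variables, the
clusterwise VAR(1) model assigns each person to exactly one of K clusters
and gives all members of cluster k a common intercept vector c_k, slope
matrix Φ_k and innovation process u_t:

    y_it = c_k + Φ_k y_i,t−1 + u_it     (person i in cluster k).

Assumptions inherited from the single-series VAR(1): equidistant
measurement intervals (for all persons), stationarity (all eigenvalues of
Φ_k inside the unit circle), innovations with constant covariance that are
uncorrelated over time but may correlate contemporaneously, and — because
clusters share one intercept — a common mean level within a cluster.
Person-mean centering (`center_panel`) removes between-person level
differences when that last assumption is implausible; in practice centered
data are the normal input and the estimated intercepts are then near zero.

Non-equidistant spacing is handled structurally, not by correction:
`read_panel` splits a person's series into segments wherever adjacent
times differ from the nominal gap, and lagged pairs are only formed inside
segments.  Rows with missing values likewise split segments; no
imputation, detrending or continuous-time correction is attempted
(deliberately out of scope).

## Estimation

Given K, the partition and the cluster models jointly minimize the pooled
squared one-step prediction error L_K (sum over persons, over within-
segment pairs, over variables).  The alternating least squares loop:

1. **Start** from a random partition (uniform assignment, redrawn until no
   cluster is empty) or the *rational* start: fit a VAR(1) per person,
   Ward-cluster the vectorized slope matrices on Euclidean distance, cut
   at K.
2. **Refit** each cluster by multivariate least squares on the vertically
   concatenated member data, B̂ = YZ′(ZZ′)⁻¹ with B = (c, Φ), dropping the
   first observation of each segment so no person's data predicts
   another's.  This equals per-equation OLS (property-tested against an
   independent per-equation solver).
3. **Reassign** persons in ascending index order: move each person to the
   cluster whose current model gives the smallest prediction error on that
   person's data, refitting the two affected cluster models immediately
   after every move.
4. **Stop** when a full sweep changes no membership (exact partition
   equality), or at `max_sweeps` (default 100; non-convergence is flagged,
   never silent).

Every move and every refit weakly decreases L_K, so the loop terminates at
a partition fixed point; monotonicity is asserted per step in a debug mode
and property-tested on random instances.  Design choices where the
procedure is underdetermined:

* **Sweep order** is fixed ascending person index, for reproducibility.
* **Ties** in the per-person error keep the current cluster, else take the
  lowest cluster index — this prevents cycling.
* **Empty-cluster veto**: a move that would empty its source cluster is
  vetoed (logged).  This preserves K and monotonicity; restarting instead
  would break determinism.
* A **batch-refit** variant (refit only after the sweep) is exposed as
  `batch_refit=True` for comparison; the default immediate refit follows
  the step-by-step update rule.
* Refits reuse cached per-person cross-products (Z′Z, Z′Y, Y′Y), so a
  sweep never touches the raw series; a person's error under coefficients
  B is tr(Y′Y) − 2tr(B′Z′Y) + tr(B′Z′ZB).  With data variances of order
  10²–10³ this cancellation costs ~5 significant digits at double
  precision, far inside the 1e-9 relative tolerances used for loss
  identities.

Multi-start: by default 100 random starts plus one rational start (the
recovery studies in `tests/` and `scripts/` use 20 + 1 as their desk
scale); the best final loss wins, ties broken by run order.  The
**attraction rate** — the share of runs whose final loss ties the best
within relative tolerance 1e-8 — is reported as a local-optimum
diagnostic.  The tolerance matters: in the hardest simulated cells
(highly similar clusters, T = 50) every run lands in a *distinct* local
optimum whose losses differ by well under 1%, so the attraction rate is
essentially 1/(number of starts) there and its mean level is sensitive to
both the tie tolerance and the start count; the factor *ordering* (worse
with more clusters, fewer time points, closer clusters, unequal sizes) is
the robust signature.  Runs that fail (a rank-deficient tiny cluster) are
excluded from the attraction denominator and logged.

Degenerate inputs: a cluster fit requires at least M + 1 lagged pairs and
a regressor cross-product matrix with reciprocal condition number above
1e-12; violations raise typed errors (`InsufficientDataError`,
`RankDeficiencyError`).  The innovation covariance estimate divides the
residual cross-products by max(N − M − 1, 1); it is diagnostic only and
never enters the loss.

## Choosing K

`select_k` fits K = K_min..K_max and applies the scree-test ratio
st_K = (L_{K−1} − L_K)/(L_K − L_{K+1}) on the lower convex hull of the
(K, L_K) points.  The hull filter (on by default, switchable off) discards
K values whose loss does not improve on K − 1 or that lie above the chord
joining their retained neighbours — both can occur when multistart
optimization is imperfect; when the hull leaves gaps, decrements are
scaled by the complexity difference they span, which reduces to the plain
ratio for consecutive K.  The maximal st wins, ties going to the smaller K
(parsimony).  A maximal ratio below 2 is flagged "no elbow": no decrement
dominates the next, as happens when the true K is 1 or losses fall
linearly.  Denominators below 1e-12 × L_K are floored and flagged rather
than allowed to produce infinities.  The interior-only definition means
K_min and K_max themselves can never be selected — the intended use is a
range that brackets the plausible K.

## Interpretation tools

`forecast` iterates ŷ_{h} = c + Φ ŷ_{h−1} with no innovations: how a
cluster returns from a given state to its baseline (I − Φ)⁻¹c (= 0 for
centered data).  `quartile_states` provides realistic low/typical/high
starting states (pooled per-variable quartiles, linear-interpolation
definition — the convention is documented because none is canonical).
`r_squared` reports per-variable one-step explained variance on pooled
pairs, 1 − SSE_m/SST_m; it uses pooled pairs (consistent with the pooled
loss) rather than per-person averaging, can be negative for a
mis-specified model, and is NaN with a warning for constant outcomes.

## Synthetic data

The generator regenerates a six-factor factorial recovery design with
M = 6 variables: number of clusters K ∈ {2, 4}; series length
T ∈ {50, 100, 500}; persons I ∈ {30, 60, 120}; cluster-separation
condition; cluster-size regime (equal; a 10% minority cluster; a 60%
majority cluster — remainders to the lowest-index clusters); innovation
regime.  Slope matrices draw diagonals from U[0.7, 0.9] and off-diagonals
from U[0.3, 0.5] (highly similar condition) or half U[0.3, 0.5] / half
U[0, 0.2], exact 15/15 split (similar condition), then rescale the whole
matrix by 0.99/max|eigenvalue| so the spectral radius is exactly 0.99 —
strongly persistent but stationary.  The highly dissimilar condition then
flips the sign of each off-diagonal entry independently with probability
1/2 (diagonals keep positive autoregression); because flips can push the
spectrum outside the unit circle, such draws are rejected and redrawn —
the flip fraction and the re-enforcement of stationarity are choices made
here, as the design leaves them open.  Innovations are multivariate normal
with unit variances and common off-diagonal covariance 0.2, or per person
0.2/0.4 with probability ½ in the unequal regime (a controlled violation
of the common-covariance assumption).  Series start at y_1 = u_1 with no
burn-in and zero intercepts; the early marginal non-stationarity is part
of the design.  Each dataset's Φ_k are drawn independently (no reuse
across cells), and person order is shuffled.

What the generator does *not* emulate about real diary data: ordinal
Likert-type scales (data are continuous Gaussian), missingness and
irregular spacing, person-level mean differences (series are mean-zero by
construction), measurement error distinct from innovations, and
quantitative within-cluster heterogeneity in Φ.  Recovery results on this
design therefore speak to the estimator under its own assumptions, not to
robustness against those features.

## Desk-scale recovery results

`scripts/acceptance.py` reruns both studies at one replication per cell
(324 and 162 datasets) with 20 random + 1 rational start — problem sizes
chosen so the whole script runs in minutes on one CPU while keeping every
design cell represented; `tests/test_acceptance.py` uses the
equal-innovation half at 10 + 1 starts with tolerances sized to the
Monte-Carlo spread of those averages.  The coefficient-recovery statistic
is reported against the *generating* slope matrices: against the
true-partition refit the distance is identically zero whenever the
partition is recovered exactly (which happens for roughly three quarters
of datasets), so the refit reference cannot underlie a strictly positive
mean distance with moderate spread; both references and
both aggregations (mean over clusters, total) are emitted in the study
table for re-aggregation.

## Known limitations

Single lag order shared by all clusters; hard (non-probabilistic)
memberships; no missing-data machinery beyond segment splitting; no
structural (contemporaneous) coefficients; exhaustive permutation matching
in the evaluator guards at K ≤ 8; the scree ratio cannot select the
endpoints of the fitted K range.
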