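# Methods

## Overview

`sconet` implements a group-comparison pipeline linking impulsive
intertemporal choice to the topology of gray-matter structural covariance
networks:

1. **Behavior.** Per subject, the hyperbolic discounting model
   `SV = A / (1 + kD)` with a logistic (softmax) choice rule
   `P(delayed) = 1 / (1 + exp(-β·ΔSV))` is fitted to intertemporal-choice
   logs by maximum likelihood. Subjects are split at the median `k` into
   high- and low-discounting groups (the unique median scorer of an odd
   cohort is excluded so groups stay balanced).
2. **Networks.** Regional gray-matter volumes are residualized against age,
   sex, education, and total intracranial volume by per-region OLS, pooled
   over the cohort. Each group's 90×90 Pearson correlation matrix over the
   corrected volumes is the weighted structural covariance network; negative
   correlations are zeroed, and the matrix is binarized at fixed sparsity
   thresholds 0.25–0.53 (step 0.01) so both groups have identical edge
   counts at every threshold.
3. **Topology.** Per binarized network: mean clustering coefficient (Cp),
   characteristic path length (Lp, averaged over connected pairs), and
   small-worldness σ = γ/λ with γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩
   normalized against 100 degree-preserving random networks. Nodal
   betweenness centrality (BC) is computed at sparsity 0.25, normalized by
   the network-average BC, and nodes above mean + 1 SD are flagged as hubs.
4. **Inference.** A permutation test relabels subjects into pseudo-groups of
   the original sizes and re-runs the full correlation → zeroing →
   binarization → metric pipeline each repetition (1,000 by default),
   yielding two-sided p-values and empirical 95% CIs for the high-minus-low
   difference of every metric at every threshold, and of normalized BC per
   region.

## Model and estimation choices

**Discounting MLE.** The likelihood is optimized over `(log k, log β)` with
L-BFGS-B, enforcing positivity without constraints. A 4×3 multi-start grid
(`log10 k ∈ {−4…−1}`, `log10 β ∈ {−4…−2}`) guards against local optima;
search bounds are `k ∈ [10⁻⁶, 10]` per day and `β ∈ [10⁻⁸, 10]`. A subject
choosing one option on every trial carries no information about the
indifference point: the fit is flagged `degenerate` with `k` pinned at the
lower bound (always-delayed) or upper bound (always-immediate) and β fitted
conditionally. `log_k` is the natural log (base-10 reported alongside).
Choice probabilities use the numerically stable log-sigmoid, so extreme
`β·ΔSV` never overflows.

**Residualization.** One OLS fit per region (intercept + four covariates)
over the pooled cohort, before the group split; residuals are exactly
orthogonal to each covariate and the operation is idempotent. A
`within_group` scope is available behind a flag. Rank-deficient covariate
designs raise an error naming the collinear columns. Sex coding (0/1 vs any
affine recoding) does not change residuals.

**Binarization.** Edge count at sparsity S is `floor(S · N(N−1)/2)` —
floor guarantees the sparsity is never exceeded and both groups get the
identical count by construction. Ties at the cutoff weight are broken
deterministically by (weight desc, row asc, column asc); this makes edge
sets exactly nested across thresholds and runs bit-reproducible. The
denominator counts all `N(N−1)/2` pairs (standard convention); requesting
more edges than there are positive correlations raises an error reporting
the achievable maximum.

**Path length on disconnected graphs.** Lp averages over pairs with finite
BFS distance; the count of infinite-distance pairs is returned and logged
rather than hidden, keeping the policy auditable. An edgeless graph raises.

**Null networks.** "Matched random networks" are produced by Maslov–Sneppen
double-edge swaps (10× the edge count of attempted swaps), conserving size,
edge count, and the exact degree sequence and never introducing self-loops
or multi-edges. Degree sequences admitting no swap (e.g. complete graphs)
return copies of the input. A density-matched Erdős–Rényi null is *not* the
default because degree-preservation is the field standard for structural
covariance studies.

**Betweenness.** Brandes' algorithm (via networkx), counting each unordered
pair once with endpoints excluded. Normalized BC divides by the network
mean, so normalized values average exactly 1 and the hub threshold is
`1 + SD` with the sample (N−1) SD. All-zero BC (complete graphs) makes hub
analysis undefined and raises.

**Permutation test.** Residualization is *not* refit per permutation: the
once-corrected volumes are relabeled, matching the design in which
correction precedes inference. p-values use the add-one estimator
`(1 + #{|null| ≥ |obs|}) / (1 + R)`, two-sided, never zero. Failed
repetitions (metric undefined on a permuted network) are excluded and
counted, not imputed. For σ inside the permutation loop the default inner
null count is 20 (configurable up to the full 100): the null means of Cp
and Lp are stable and the full setting would cost 29 × 1,000 × 100 rewiring
runs. Nodal results carry two flags: nominal `p < 0.05` and the node-count
correction `p < round(1/N, 3)` (0.011 for 90 regions).

**Cohort statistics.** The demographic table uses the pooled-variance
two-sample t (df = n₁ + n₂ − 2) and the Pearson chi-square without
continuity correction — the conventions that reproduce the reference
cohort's printed values (e.g. χ² = 0.521 for a 21/14 vs 18/17 sex split).

## Synthetic data

No subject-level data are distributable, so every stage is exercised on a
generator with known ground truth.

**Choices** are drawn from the hyperbolic/softmax model itself on the task
grid: fixed ₩10,000 immediate option, delayed amounts in ₩1,000 steps over
[₩11,000, ₩48,000], delays 2–180 days, 120 trials per subject. Cohort
draws use per-subject `k` log-uniform over [0.001, 0.1] per day with
β = 0.005 (a slope that yields realistically stochastic choice on this
value scale).

**Morphometry** comes from a nested community factor model: 90 regions in
6 equal communities; every region loads `b` (= 0.3) on a global factor and
each community adds its own factor with loading `√(w² − b²)` so the total
within-community shared scale is `w` (= 1.0 by default), plus unit-SD
noise. The implied correlations are `w²/(w² + σ²) = 0.5` within and
`b²/(w² + σ²) = 0.045` between communities — closed-form oracles used
directly in tests (`analytic_correlation`). Requiring `w ≥ b` keeps the
implied covariance positive semidefinite; violations raise at config time.
Covariates are drawn on young-adult scales (age 22 ± 2.7 y, education
15 ± 1.3 y, TIV 1550 ± 150) and enter as per-region slopes, giving the
residualization stage a real confound to remove.

**Scenarios.** `null` draws both groups from the identical model — used for
type-I-error calibration. `planted` lowers the high group's
within-community loading to 0.35 (global loading unchanged), making its
network relatively more integrated and noise-dominated: lower clustering
*and* shorter paths across the whole sparsity range, the direction of the
group effect this pipeline is designed to detect. Under the defaults both
groups remain in the small-world regime (σ > 1, with γ > 1 and λ ≈ 1) at
every threshold in 0.25–0.53.

**What the generator does not emulate:** spatial smoothness and cortical
geometry, hemispheric symmetry of real parcellations, non-Gaussian volume
distributions, site/scanner effects, and any true coupling between a
subject's discount rate and their covariance structure beyond the planted
group labels. Passing tests therefore demonstrate the *statistical
machinery* (calibration, recovery, exactness of graph metrics), not
neurobiological validity on real data.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to exercise the full pipeline
while keeping the suite practical: type-I calibration uses 200 null
datasets × 200 permutations at one threshold; planted-effect recovery uses
200 permutations across all 29 thresholds; discount-rate recovery uses 200
simulated subjects; graph-metric exactness uses 200 random graphs of ≤ 12
nodes against enumeration oracles. The full printed settings (1,000
repetitions, 100 nulls everywhere) remain the library defaults.

## Known limitations

- Weighted-network metrics, efficiency/modularity, and FDR beyond the two
  fixed thresholds are out of scope.
- σ normalization inside permutations defaults to 20 nulls (documented in
  output metadata); observed-network σ always uses the full 100.
- The median split requires a unique median scorer in odd cohorts; broader
  ties raise rather than guess.
- Characteristic path length on fragmented networks averages finite pairs
  only; at the default sparsity range the synthetic networks stay
  connected, so the policy rarely engages.
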