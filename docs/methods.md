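# Methods

## Model

`bmrfnet` treats a standardized n × p expression matrix as draws from a
Gaussian graphical model and infers the network through the conditional
(CAR) parameterisation: for each gene j,

    X_j | X_(−j) ~ N( Σ_{k≠j} β_jk X_k , σ_j² ).

When the precision matrix has a constant diagonal, β_jk = β_kj, so each
unordered pair carries one strength coefficient; β_jk = 0 if and only if
the partial correlation ρ_jk = −ω_jk/√(ω_jj ω_kk) is zero, i.e. the edge
is absent. The fitted likelihood is the **symmetric pseudo-likelihood**:
the product of the p conditional Gaussians with the shared β. This is the
objective a BUGS-style encoding of the conditional model maximizes; the
exact joint MVN likelihood would require constraining Ω to stay positive
definite, which the conditional specification never enforces. Both views
coincide at the true parameters; for finite data the pseudo-likelihood is
a consistent, slightly less efficient surrogate.

Priors, per candidate pair:

* β_jk | γ_jk ~ γ ψ₁ + (1−γ) ψ₀ with ψ_g Laplace densities of rate
  τ₁ = 2 (slab) and τ₀ = 20 (spike). These defaults put the spike's mass
  inside |β| ≲ 0.1 and leave the slab essentially flat over the range of
  realistic CAR coefficients (|β| ≤ 1); the posterior ranking of edges is
  insensitive to moderate changes in these rates.
* γ_jk ~ Bernoulli(p_jk), p_jk ~ Beta(a_jk, b_jk). Flat Beta(1,1)
  (mean 0.5) in the objective setup; Beta(8,2) (mean 0.8, concentration
  10) on informative pairs in the data-driven setup. The concentration 10
  makes ten pseudo-observations of prior belief — enough to matter, weak
  enough for the data to overrule.
* σ_j² ~ inverse-gamma(0.01, 0.01), the standard vague conjugate choice.

The posterior mean of γ_jk is the edge-existence probability; edges with
probability > 0.5 (configurable; 0.7/0.9 useful for stricter maps) form
the reported network.

## Sampler

One Gibbs sweep updates:

1. each candidate β_jk exactly: the pseudo-likelihood contributions of
   rows j and k are jointly Gaussian in β_jk, so under a Laplace
   component the full conditional is a two-piece truncated normal; the
   piece is chosen by its log-space normalizing mass and sampled by
   Robert's exponential-rejection truncated-normal method. A random-walk
   Metropolis update (`beta_update="metropolis"`) is kept as a fallback
   for extreme rate values; the two kernels agree within Monte-Carlo
   error on test problems.
2. γ_jk from its Bernoulli conditional (slab weight of the two Laplace
   densities, computed in log space);
3. p_jk from the conjugate Beta;
4. σ_j² from the conjugate inverse-gamma.

Non-candidate coefficients stay fixed at zero. Defaults: 10,000
iterations, 5,000 burn-in, thin 1, initialization β = 0, γ = 0, p_jk at
its prior mean, σ² = 1. Chains on the benchmark problems (p ≤ 50, a few
hundred candidate pairs) mix within a few hundred sweeps under these
conjugate-style updates; the exactness of the β update removes all
tuning. Residual vectors are maintained incrementally and refreshed every
1,000 sweeps against floating-point drift; a non-finite log
pseudo-likelihood aborts with the failing iteration. All draws are
reproducible from the configuration seed. The kernel is compiled with
numba; a fit of the p=25 benchmark takes ~1–2 s on one CPU.

Correctness of the sampler is established against an independent oracle:
for p ≤ 3 the posterior P(γ_jk = 1) is computed by enumerating all
indicator configurations and integrating the strengths on a Simpson grid
(conditional variances and inclusion probabilities integrate out
analytically); the chain agrees within 3 Monte-Carlo standard errors
(batch-means estimate, plus a 0.005 allowance for the quadrature
resolution).

## Candidate pairs and prior elicitation

Sampling every one of the p(p−1)/2 pairs is supported
(`EdgePriorSpec.noninformative(p)`), but the default workflow restricts
attention to screened candidates, which both saves computation and acts
as a first regularization stage:

* **G\*** — the pairs with the largest absolute Pearson correlations; the
  kept fraction is 10% of all pairs (15% for the denser S = 0.10
  benchmark regimes). Ties break lexicographically, so the mask is
  deterministic.
* **M\*** — a sparse neighborhood screen: lasso regression of each gene
  on all others (penalty √(2 log p / n), the classical
  neighborhood-selection order) with the OR rule. Any externally
  computed mask (e.g. a joint sparse-regression estimate or expert
  knowledge) can be supplied instead, as an edge list or adjacency file.

BMRF.O uses G* as the candidate set with flat priors. BMRF.P uses
G* ∪ M* as candidates with the informative prior on G* ∩ M*. In
benchmark pilots the all-pairs objective variant over-selected (false
discovery ≈ 0.3 at p = 25) while the screened candidate set matched the
published operating characteristics of the method, so screening is the
default for both setups at every p.

## Simulators

Three regimes, all with default sample size n = 250 and data drawn as
MVN(0, Ω⁻¹) via the Cholesky factor of Ω:

* **M1 (random)** — each pair is an edge with probability S
  (presets: p = 25/50 × S = 0.05/0.10). Edge entries of Ω are drawn
  uniformly on [−1, −0.05] ∪ [0.05, 1] (sign ± with equal probability,
  magnitude uniform — measure-equivalent and separately testable), each
  row's off-diagonal entries are divided by 1.5× the row's absolute sum,
  and the matrix is symmetrized by averaging with its transpose. The
  rescaling leaves every off-diagonal row sum at 2/3 < 1 against a unit
  diagonal, so the matrix is strictly diagonally dominant, hence positive
  definite; the division is interpreted row-wise, the only reading that
  guarantees this.
* **M2 (scale-free)** — a preferential-attachment tree (one edge per new
  node, exactly p − 1 edges, hubs emerge), with Ω = I + 0.216·A so every
  edge has partial correlation −0.216. The uniform edge strength
  isolates structure recovery; it mirrors the fixed-network regime
  because no separate strength value is published for this family.
* **M3 (fixed two-hub)** — a deterministic 50-node tree with hubs of
  degree 14 ("Node-2", index 1) and 7 ("Node-4", index 3), 49 edges,
  same homogeneous Ω. The two hub degrees are the only published
  quantitative constraints on this topology; the remaining nodes attach
  by a fixed-seed preferential scheme, with the hubs joined through an
  intermediate node to keep the adjacency spectrum inside the positive-
  definiteness bound |ρ| < 1/λ_max(A) (here λ_max ≈ 3.98 < 1/0.216 ≈ 4.63).

What the simulators emulate is the *dependence structure* benchmark:
Gaussian data, exact sparsity, homogeneous or bounded edge strengths.
Real expression data violate all three (non-normal margins, batch
effects, hub strengths that vary by orders of magnitude), so passing
benchmarks demonstrates correct recovery of conditional-dependence
structure under the model's assumptions, not performance on any
particular real dataset.

## Evaluation

Estimated networks are scored over all unordered pairs: TP/FP/FN/TN,
sensitivity, specificity, FDR, MCC and F1 (zero-denominator conventions:
FDR = 0 with no positives, MCC = F1 = 0 when undefined — this keeps
replication summaries finite). The Brier score averages
(indicator − probability)² over **all** pairs, with non-candidate pairs
as probability-0 predictions: a true edge lost in screening is charged a
full unit of error, so screening quality is part of the calibration
measure. `run_replication_study` repeats simulate → screen → fit → score
with seeds derived deterministically from a base seed and reports means
with standard errors (SD/√R).

Replication counts used by the test suite and the acceptance script are
R = 20 for the random-network study and R = 10 for the fixed-network
study, with the default 10,000-iteration chains — small enough to run in
a couple of minutes, large enough that the mean metrics stabilize to
within their standard errors.

## Numerical choices and degenerate inputs

* Symmetry tolerance 1e-10 and positive definiteness via the smallest
  eigenvalue for precision-matrix validation (cheap at p ≤ 100).
* Standardization uses the unbiased (n−1) variance; constant genes raise
  an error naming the gene. Standardization is idempotent to 1e-12.
* log Φ in the β update switches to the asymptotic tail expansion below
  z = −37, where erfc underflows.
* Correlation screening keeps exactly ⌈fraction × pairs⌉ pairs regardless
  of ties (stable sort, lexicographic tie-break).
* Derived per-replication seeds come from a seeded integer stream and
  stay below 2³¹.

## Known limitations

* The pseudo-likelihood ignores the positive-definiteness coupling across
  pairs; posterior strength summaries are per-edge, not a joint precision
  estimate.
* The existence probability is conditional on the screened candidate set;
  pairs outside it get probability zero by construction.
* The neighborhood screen is a generic lasso OR-rule stand-in for more
  elaborate joint sparse-regression estimators; users wanting a specific
  estimator should supply M* themselves.
* Runtime grows with candidate pairs × n per sweep; panels beyond a few
  hundred genes would need screening plus longer runs.
* Gaussianity is assumed throughout; heavy-tailed expression data should
  be transformed first.
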