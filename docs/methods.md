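# Methods

## Model

The Long-DINA model stacks three levels. The measurement level is the
conjunctive DINA item response function: with binary Q-matrix entries
q_ikt, the ideal response η_nit = ∏_k α_nkt^q_ikt (0⁰ = 1, so items ignore
attributes they do not measure) and

    logit P(y_nit = 1) = λ0_it + λ1_it · η_nit.

λ0 is the guessing logit, λ0 + λ1 the non-slipping logit; λ1 > 0 is
enforced throughout so mastery can never lower the success probability.
The attribute level is a higher-order logistic model,
logit P(α_nkt = 1) = β_k·θ_nt − δ_k, with slopes and difficulties invariant
over occasions. The growth level places θ_n ~ MVN(μ, Σ) over occasions,
with μ₁ = 0 and Σ₁₁ = 1 as scale-identification constraints; later means,
standard deviations and all correlations are free. With T = 1 the model is
the cross-sectional higher-order DINA model.

Anchor items are internal: their Q-matrix row and (λ0, λ1) pair are
identical at every occasion, and the estimator treats each anchor as a
single parameter block pooling likelihood contributions over occasions.

## Generating configuration (simulator defaults)

The simulator reproduces one fixed study design; its defaults are the study
conditions, not tuning knobs.

| quantity | default | meaning |
|---|---|---|
| K | 4 | attributes |
| T | 3 (4 in the supplementary grid) | occasions |
| I | 20 or 30 | items per occasion |
| N | 100 or 500 | persons |
| (λ0, λ1) mean | (−2.197, 4.394) | guessing/slipping ≈ 0.1 at the mean |
| (λ0, λ1) covariance | unit variances, corr −0.6 | moderate negative guessing–slipping link |
| β | (−1, −0.5, 0.5, 1) | higher-order slopes |
| δ | 1.5 (all k) | higher-order difficulties |
| ability corr | 0.9 | between any two occasions |
| mean growth | 0.5 per interval | μ = (0, 0.5, 1.0) |
| scale change | 1.25 per interval | sd = (1, 1.25, 1.5625) |

Each Q-matrix is built as (R, R, Q*): two leading 4×4 identity blocks (the
unit Q-matrices that make every attribute identifiable) followed by rows
drawn i.i.d. uniformly, with replacement, from the 11 patterns of weight
≥ 2. Non-anchor rows and item parameters are redrawn per occasion —
different test forms share only the anchors — and everything is regenerated
per replication. λ1 draws ≤ 0 (probability ≈ 6×10⁻⁶) are
rejection-resampled. Anchor designs follow the tabulated Study 1
(which items are anchors, relative to the identity blocks) and Study 2
(anchor ratios 0–80%) conditions exposed by `build_anchor_design`.

What the generator does *not* emulate: missing responses, item-parameter
drift, attribute hierarchies, Q-matrix misspecification, polytomous
responses, local dependence among anchors. Passing tests therefore speak to
the model's behaviour under a correctly specified, complete-data design,
not to robustness against any of those violations.

## Estimation

A Metropolis-within-Gibbs sampler, vectorized over persons and item blocks.
Priors are weakly informative and centred on a realistic item-quality
regime: λ0 ~ N(−2.197, 1); λ1 ~ N(4.394, 1) truncated positive;
β_k, δ_k, μ_t ~ N(0, 2²); σ_t half-normal(2); correlations uniform over the
positive-definite region.

Update scheme per iteration:

* **α_nkt** — exact Gibbs from the Bernoulli full conditional combining the
  item likelihood (only items whose other requirements are met contribute)
  and the higher-order prior.
* **Item blocks** — scalar random-walk Metropolis on λ0 then λ1, vectorized
  across all blocks (non-positive λ1 proposals rejected).
* **θ_nt** — per-occasion random-walk Metropolis against the attribute
  likelihood and the MVN conditional prior.
* **β_k, δ_k** — scalar random-walk Metropolis.
* **μ (t ≥ 2)** — exact Gibbs from the conjugate normal full conditional.
* **σ_t** — log-scale random walk; **correlations** — Fisher-z random walk
  (efficient near the boundary, where the generating value 0.9 lives).

Three further moves address the ridges a hierarchical latent model creates.
Per occasion, a translation move shifts (θ_·t, μ_t) together and a rescale
move scales (θ_·t − μ_t, σ_t) together in the non-centred parameterization;
globally, a rescale move maps (β, θ, μ, σ) → (cβ, θ/c, μ/c, σ/c), under
which the attribute-level likelihood is exactly invariant. Each uses the
exact posterior ratio with the appropriate Jacobian. The (θ, structural)
blocks are cheap relative to the item scan, so they are swept
`n_inner_sweeps` (default 3) times per iteration.

Sign identification: the model is exactly invariant under
(θ, β, μ) → (−θ, −β, −μ). The sign is pinned by constraining one slope
(`sign_attr`, default the last attribute) to be positive — a hard
truncation would still leave a trap where that slope is squeezed toward 0⁺
with everything else mirrored, so a reflection mode-jump move (an
involution flipping θ, μ and all *other* slopes) lets a chain that starts
in the mirror basin escape while being firmly rejected in the correct one.
Label switching across attributes is structurally absent: the identity
blocks in the Q-matrix tie each attribute to its own items.

Proposal scales adapt toward 44% acceptance during burn-in only and are
frozen afterwards, so retained draws come from a fixed transition kernel.
Chains start overdispersed (parameters drawn around their priors, random
attribute profiles). Run lengths: the full protocol is 2 chains × 10,000
iterations with 5,000 burn-in; the desk-scale protocol
(`MCMCSettings.reduced()`) is 2 × 3,000 with 1,500 burn-in, used for the
replication studies so a full condition grid stays tractable on one CPU.

Correctness checks built into the test suite: a no-data run reproduces the
prior marginals (detailed balance across every structural move including
the group moves); on K=1, T=1 toys with parameters clamped
(`fixed_items`/`fixed_struct`), MCMC mastery posteriors match exhaustive
enumeration with Gauss–Hermite quadrature within 0.02.

## Convergence and classification

The classic Gelman–Rubin PSRF — sqrt(((L−1)/L·W + B/L)/W) — is computed
per monitored parameter (all item and structural parameters, not
person-level latents); two identical chains give sqrt((L−1)/L), reported
as-is. A split-chain option exists but is off by default to mirror the
two-chain protocol. Replications with any PSRF > 1.2 are flagged in
reports, never dropped.

Classification is the marginal posterior mode per attribute: mastery iff
the pooled posterior mastery probability ≥ 0.5 (ties go to mastery).
ACCR/PCCR/LPCCR pool indicator counts across replications before dividing
(denominator N×Re). Pooled ACCR across cells is the equal-weight mean of
the per-attribute, per-occasion rates. Condition contrasts report
differences with binomial standard errors on the pooled denominators and
flag differences beyond 3 SEs.

## Numerical choices and edge cases

* Logistic quantities go through `scipy.special.expit`/`log_expit`; no
  hand-rolled exponentials.
* The brute-force marginal-likelihood oracle exploits the factorization of
  the attribute sum over occasions given θ, enumerates the 2^K profiles per
  occasion, and integrates θ with a tensor-product Gauss–Hermite rule
  (≥ 15 nodes per dimension) or a seeded Monte-Carlo fallback; it refuses
  K·T > 12.
* Degenerate inputs: zero items or zero persons yield empty structures, not
  errors; an all-zero or all-one response column is legal.
* All user-facing indices (items, occasions, attributes, persons) are
  1-based in files and parameter names; arrays are 0-based internally.
* Per-replication seeds derive from `numpy.random.SeedSequence(master,
  study, cell, rep)`, so cells and replications are reproducible and
  independent.

## Problem sizes used in the shipped checks

The shipped test suite and acceptance script run at desk scale, chosen so
the whole suite completes in minutes on one CPU: single fits at N=100/I=20
and N=500/I=30 under the reduced protocol, and the anchor-equivalence
contrast (Study 2, 0% vs 80% anchors, I=20, N=100) at 5 replications per
condition. The full protocol (100 replications, 10,000/5,000 iterations,
all 20 cells per study) is available through `StudyGrid`/`MCMCSettings` and
the `--full-protocol` CLI flag.

## Known limitations

* The reduced protocol leaves the growth-level posterior noticeably wide at
  N=100; mean-growth estimates stabilize at N=500.
* Individual higher-order slopes with small |β| are weakly identified in
  short tests; their chains can disagree across runs even when every item
  parameter has converged.
* The binomial SEs used in condition contrasts ignore the within-replication
  clustering of classification indicators and are therefore mildly
  anti-conservative.
* No model-fit indices (DIC, posterior predictive checks) are computed —
  convergence diagnostics only — and no variational or EM estimator is
  provided.
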