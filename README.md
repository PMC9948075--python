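# longdina

Simulation and fully Bayesian estimation of the **longitudinal higher-order
DINA (Long-DINA)** diagnostic classification model, built to study a design
question in longitudinal learning diagnostic assessment: *do anchor items —
and in particular anchor items carrying a unit Q-matrix — matter for
classification accuracy?*

## Who this is for

Psychometricians and methodologists working with diagnostic classification
models (DCMs) over repeated test administrations. Different test forms at
different occasions are conventionally linked through shared *anchor items*;
this package provides the machinery to ask, by simulation, whether that
convention matters when the latent constructs are discrete attributes.

## The model

For person *n*, item *i*, occasion *t*, with binary attributes
α<sub>nkt</sub> (k = 1…K) and Q-matrix entries q<sub>ikt</sub>:

* **Measurement (DINA):**
  logit P(y<sub>nit</sub> = 1) = λ<sub>0it</sub> + λ<sub>1it</sub> ∏<sub>k</sub> α<sub>nkt</sub><sup>q<sub>ikt</sub></sup>,
  so the success probability jumps from the *guessing* level
  logit⁻¹(λ<sub>0</sub>) to 1 − *slipping* = logit⁻¹(λ<sub>0</sub> + λ<sub>1</sub>)
  only when all required attributes are mastered (λ<sub>1</sub> > 0).
* **Attribute structure (higher order):**
  logit P(α<sub>nkt</sub> = 1) = β<sub>k</sub> θ<sub>nt</sub> − δ<sub>k</sub>,
  one continuous general ability driving all attributes.
* **Growth:** θ<sub>n</sub> = (θ<sub>n1</sub>, …, θ<sub>nT</sub>) ~ MVN(μ, Σ),
  with μ₁ = 0 and Σ₁₁ = 1 for identification. With T = 1 this reduces to the
  cross-sectional higher-order DINA model.

Anchor items keep their Q-matrix row *and* their (λ<sub>0</sub>, λ<sub>1</sub>)
pair identical at every occasion; the estimator gives each anchor a single
shared parameter block.

Estimation is by a self-contained, vectorized Metropolis-within-Gibbs
sampler (no external Bayesian engine); convergence is monitored with the
classic Gelman–Rubin PSRF. Classification uses the marginal posterior
mastery probability per attribute (EAP ≥ 0.5). Accuracy is summarized by
ACCR (per attribute), PCCR (whole profile per occasion) and LPCCR (whole
K×T array across occasions).

## Worked example

```python
from longdina import (SimulationConfig, MCMCSettings, build_anchor_design,
                      simulate_dataset, run_mcmc, classify_attributes, accr, lpccr)

design = build_anchor_design(study=1, condition_id=2, n_items=20)  # anchors = items 1-4 (one unit block)
cfg = SimulationConfig(n_persons=100, n_items=20, seed=1, design=design)
data = simulate_dataset(cfg)

result = run_mcmc(data.responses, data.qmat, design, MCMCSettings.reduced(seed=101))
cls = classify_attributes(result)

print("fraction of parameters with PSRF <= 1.1:", (result.psrf <= 1.1).mean())
print("pooled ACCR:", accr(data.persons.alpha, cls.alpha_hat).mean().round(3))
print("LPCCR:", round(lpccr(data.persons.alpha, cls.alpha_hat), 3))
print("estimated mean growth mu_2:", round(result.posterior_mean["mu[2]"], 3))
```

Output:

```
fraction of parameters with PSRF <= 1.1: 0.9915966386554622
pooled ACCR: 0.92
LPCCR: 0.34
estimated mean growth mu_2: 0.555
```

All 119 monitored item/structural parameters are checked for convergence;
92% of the 1,200 attribute statuses are classified correctly, 34% of
persons have all 12 statuses correct, and the posterior mean growth between
the first two occasions is near the generating value 0.5 (N = 100 leaves it
noisy; N = 500 pins it down).

The same workflow is scriptable from a shell (`longdina simulate`,
`longdina fit`, `longdina evaluate`, `longdina run-study`); see
`longdina --help`.

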