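# longdcm

Longitudinal diagnostic classification models (DCMs) with hierarchical
attributes: Q-matrix design diagnostics, maximum-likelihood estimation of the
transition DCM (TDCM) and its hierarchical form (H-TDCM), and Monte Carlo
classification-accuracy studies.

## The problem

Formative classroom assessment tracks which fine-grained skills
("attributes") each student has mastered across repeated short tests.  A
student's state is a binary attribute profile α ∈ {0, 1}^K; a prerequisite
hierarchy (e.g. the linear chain α₁ → α₂ → α₃) shrinks the space of
permissible profiles from 2^K to, say, K + 1.  Items relate to attributes
through a Q-matrix (items × attributes), and responses follow the log-linear
cognitive diagnosis model (LCDM):

P(X_i = 1 | α) = logit⁻¹( λ_{i,0} + Σ_S λ_{i,S} ∏_{k∈S} α_k ),

with an intercept, main effects, and interactions over the attributes item i
measures.  Over T occasions the profile follows a first-order Markov chain
with initial prevalence δ and transition matrices τ, giving the marginal
likelihood of a response record y:

P(Y = y) = Σ_{c₁…c_T} δ_{c₁} τ_{c₂|c₁} ⋯ τ_{c_T|c_{T−1}} ∏_{t,i} P(y_{i,t} | α_{c_t}).

The **H-TDCM** imposes the hierarchy on this model: the latent space is
restricted to permissible profiles and redundant measurement effects are
fixed at zero (for a full three-attribute item under a linear hierarchy only
the intercept, the first main effect, and the nested interactions survive —
four free parameters instead of eight).  The package estimates both variants
by EM with exact forward–backward smoothing, classifies examinees by MAP over
the per-occasion posterior, and audits Q-matrix designs for identifiability:
how many copies of the transposed reachability matrix R^T a design contains,
and whether the induced Γ-matrix (items × profiles indicator of maximal
success probability) has all-distinct profile columns ("separable"), a
necessary condition for strict identification.

## Worked example

```python
from longdcm import (AttributeHierarchy, ModelSpec, StudyDesign,
                     classify, fit_em, profile_ccr, simulate_dataset)

h = AttributeHierarchy.linear(3)                      # α1 → α2 → α3
design = StudyDesign(hierarchy=h, design_id="Q2",     # R^T + identity + fill
                     n_examinees=1000, base_seed=3)
responses, truth = simulate_dataset(design, rep=0)

spec = ModelSpec(hierarchy=h, qmatrix=design.qmatrix, variant="htdcm", n_times=3)
fit = fit_em(responses, spec, n_starts=3, seed=3)
est, posterior = classify(fit.model, responses)
print(fit.loglik, [profile_ccr(truth, est, t) for t in range(3)])
```

Running `python examples/fit_longitudinal_model.py` (same setup) prints

```
H-TDCM: logL=-17649.2  free params=51  AIC=35400  converged=True
TDCM:   logL=-17635.7  free params=149  AIC=35569  converged=True
LRT: statistic=27.00  df=98  p=1.000
H-TDCM profile CCR by occasion: [0.782 0.816 0.806]
```

The hierarchical model uses a third of the parameters, loses almost no
likelihood on hierarchy-consistent data (the likelihood-ratio test is far
from significant), and recovers ~80% of profiles exactly with a 10-item
test.  The other scripts in `examples/` demonstrate Q-matrix auditing,
the learning-kernel simulator, and the multi-condition study runner; the
`longdcm` console command (`qaudit`, `simulate`, `fit`, `study`) exposes the
same operations on CSV/YAML files.

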