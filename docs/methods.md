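# Methods

`kiteipm` implements an integrated population model (IPM) for a small,
closed island population of Red Kites (*Milvus milvus*) subject to
illegal poisoning, together with the deterministic perturbation analysis
that translates cause-specific mortality into its effect on population
growth. This note records the model, the numerical choices, and what the
synthetic-data tests do and do not establish.

## The integrated model

Four data streams are joined through one likelihood with shared
parameters (assumed mutually independent given those parameters):

1. **Radio-tracking histories** (multistate capture-recapture).
   Individuals tagged as nestlings move through 16 latent states
   combining six age classes for live birds, radio status, cause of
   death (poison vs other), and an absorbing unobserved-dead state.
   Annual survival φ is age- and sex-independent; conditional on death,
   the poison fraction m_a is age-dependent (juvenile, 1-yr, 2+);
   radio-signal retention ρ_k follows three tag-age classes (battery
   life 3–4 yr); detection is p with a working radio, pA without; dead
   birds without a radio are reported with rate rP (poison) or rO
   (other), while a working radio makes a carcass certain to be found.
   The likelihood is evaluated by the exact forward algorithm over the
   16 states — no latent-state augmentation — conditioning on release
   alive with radio as a juvenile. Male histories enter identically;
   they only sharpen the shared parameters.
2. **Breeding-pair counts** (state-space model). The latent female
   population has three classes (1-yr N1, 2-yr N2, older N3).
   Recruitment is Poisson with mean φ·(f_t/2)·B_t, ageing/survival are
   Binomial thinnings, and the count of breeding pairs is Poisson around
   the expected breeders B_t = β₂N2 + γN3. β₂ = 0.1 is a fixed field
   constant (about 10 % of 2-yr females breed); γ, the breeding
   proportion of older females, is a latent parameter with no direct
   data.
3. **Productivity.** Yearly fledgling totals are Poisson with mean
   R_t·f_t (R_t surveyed broods); log f_t ~ Normal(μ, σ²) is a
   random-year effect. Fecundity is per pair and halved only inside the
   female population model (even fledgling sex ratio).
4. **Dead recoveries of unmarked birds.** Each year the population
   partitions multinomially into died-by-poison, died-otherwise and
   survived, with cell probabilities ((1−φ)m̄, (1−φ)(1−m̄), φ), where m̄
   is the arithmetic mean of the three m_a. Reported carcasses are
   Binomial thinnings of the latent death counts with rates rP, rO —
   the link that makes this very sparse series informative about the
   reporting rates.

Model variants nest: `MS` (stream 1 only), `IPM1` (1–3), `IPM2` (all
four).

### Priors

Uniform(0,1) for all probabilities; γ ~ Uniform(0.5, 1) by default, with
the two truncated-normal alternatives (mean 0.75, variance 1000; mean
0.5, variance 0.25; both truncated to [0.5, 1]) available for the
sensitivity check; μ ~ Normal(0, 100); σ ~ Uniform(0, 10). Initial
population classes get either independent truncated Poisson(10) priors
(the default, scaled to the observed handful of pairs) or a flat
discrete-uniform over {0..max}. The flat option exists because a Poisson
is *not* weakly informative once the population is large: in scaled-up
recovery experiments the narrow Poisson distorted the early latent
trajectory and pushed γ onto its lower prior bound. Fits to data at
other scales should use the uniform option with an appropriate cap.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs. Continuous parameters get
Gaussian proposals on their natural scale (rejected outside bounds,
which is equivalent to the uniform prior restriction); latent integer
counts get symmetric integer proposals of magnitude ⌈s·|z|⌉ with z
standard normal. All step sizes s adapt toward 0.44 acceptance by a
Robbins–Monro recursion during burn-in only, preserving the correct
stationary distribution afterwards. Component log-likelihoods are cached
and only the terms a site touches are recomputed. Default run lengths
(3 chains × 50,000, burn-in 25,000, thin 5) are desk-scale; the original
analysis used 3 × 1,000,000 / 500,000 / 20, available via config. Runs
are bit-reproducible given the seed (per-chain seeds are spawned from
one `SeedSequence`).

Convergence is assessed by the split potential-scale-reduction statistic
(threshold 1.1, the conventional criterion); parameters above threshold
are warned about and listed in the run metadata, never silently passed.

### Derived quantities

Per posterior draw: year-specific growth λ_t = N_tot,t+1/N_tot,t and
their geometric mean; poison-free survival φ*_a = φ + (1−φ)m_a
(additive-mortality assumption); the proportional reduction
Δ_a = 1 − φ/φ*_a. Forward projection re-simulates the stochastic state
process from the final latent state per draw, drawing future fecundities
from the fitted year effect.

## Deterministic perturbation analysis

The female pre-breeding projection matrix is

    A = [ 0          β₂(f/2)φ_juv   γ(f/2)φ_juv ]
        [ φ_1y       0              0           ]
        [ 0          φ_2my          φ_2my       ]

with φ_a = φ*_a(1−Δ_a). Fertility on the 2-yr class (×β₂) and the 3+
class (×γ), each carrying first-year survival because the census is
pre-breeding. This structure reproduces the published 8.2 % growth, the
break-even reductions and survivals, and (as it turned out) essentially
the full published sensitivity/elasticity table, which is why it is
canonical here; the alternative placement of the β₂ term on the 1-yr
class is available via `build_matrix(..., beta2_on_first_class=True)`
for comparison but does not reproduce the published growth rate.

Growth rate is the dominant eigenvalue (dense solver; validated against
the characteristic polynomial in tests). Matrix-element sensitivities
are s_ij = v_i w_j /⟨v,w⟩; elasticities (a_ij/λ)s_ij sum to one.
Lower-level vital-rate sensitivities use the exact chain rule through
the matrix cells and are cross-checked against central finite
differences (step 1e-6) in tests only; absolute values are reported
because the derivatives for the Δ_a are negative by construction.
Break-even reductions solve λ(Δ_a) = 1 by Brent's method on [0, 1]
(tolerance 1e-8), holding other classes at their current reductions; an
absent sign change is reported as unattainable rather than clamped.

## Synthetic data: what it emulates and what it does not

The generator simulates the exact generative mirror of every likelihood
component at a stated parameter point (defaults: the full-model
posterior means — φ=0.808, m=(0.428, 0.764, 0.764), ρ=(0.862, 0.333,
0.045), p=0.990, pA=0.328, rP=0.461, rO=0.075, γ=0.631, exp(μ)=1.825,
σ²=0.110) and a stated design: 12 survey years, 11 annual cohorts of 13
radio-tagged fledglings (~143 birds, tagging starting one year after
surveys), ~50 % males contributing only to the tracking stream, an
initial population of (3, 3, 10) females giving ~7 breeding pairs, and a
sparse recovery series (order 0–2 carcasses per year). A `scale`
operation multiplies cohort sizes and the initial population for power
studies without touching any rate.

Because simulator and likelihood share the same model, green recovery
tests establish *internal* consistency — the sampler targets the
posterior implied by the written likelihood — not that the model
describes real kites. Real data would add overdispersion in counts,
inter-individual heterogeneity in survival and detection, partial
dependence between streams (the study's own caveat) and possibly
misclassified causes of death; none of these are simulated.

One structural ambiguity inherited from the source analysis: the
recovery multinomial uses the *female* latent total as its sample size,
while real carcasses come from both sexes. The module keeps the
female-based total (matching the original model's single population
vector); treat the estimated reporting rates as conditional on that
convention.

## Known limitations

- No immigration/emigration (closed island assumption), no time-varying
  survival or detection, no density dependence, no stochastic
  (environmental-variance) growth rate.
- The single-site random-walk sampler is robust but not fast; strongly
  coupled blocks (γ with the N3 trajectory) mix on thousands, not
  hundreds, of iterations. The recovery tests therefore run few, short
  chains and check coverage against a binomial floor rather than
  per-replicate.
- Histories must begin at tagging as nestlings (event 1); adult-tagged
  birds are outside the state space.
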