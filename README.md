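# kiteipm

Integrated population modelling of poison-related mortality in the Red
Kite (*Milvus milvus*) population of Mallorca — and, more generally, a
worked, tested implementation of the four-stream IPM + perturbation
workflow for small raptor populations monitored by heterogeneous data.

Illegal poison baits are a leading cause of death for European
scavenging raptors. For a small island population, no single data
source — a census of ~8–19 breeding pairs, ~143 radio-tagged
fledglings, brood surveys, a handful of carcasses reported by the
public — is informative enough on its own. This package joins all four
in one Bayesian model with shared parameters, then asks the management
question with a deterministic Leslie matrix: *how much is poisoning
costing the population in growth, and how much more would tip it into
decline?*

## The model in brief

Four likelihood components share parameters (independence assumed):

- **Multistate capture–recapture** over 16 latent states (6 age classes
  alive-with-radio, 5 alive-without, 4 recently-dead by cause × radio
  status, 1 absorbing unobserved-dead): age-independent annual survival
  φ, age-specific poison fractions m_a (a ∈ {juv, 1y, 2+}), tag-battery
  retention ρ₁..ρ₃, detections p, pA, reporting rates rP, rO. Exact
  forward-algorithm likelihood.
- **Count state-space model**: latent female classes (N1, N2, N3) with
  Poisson recruitment φ·(f_t/2)·B_t, binomial survival, and Poisson
  counts around the expected breeders B_t = β₂N2 + γN3 (β₂ = 0.1 fixed;
  γ latent).
- **Productivity**: J_t ~ Poisson(R_t·f_t), log f_t ~ N(μ, σ²).
- **Dead recoveries**: yearly deaths multinomial with cells
  ((1−φ)m̄, (1−φ)(1−m̄), φ), reported carcasses binomially thinned with
  rP, rO.

Variants `MS` ⊂ `IPM1` ⊂ `IPM2` add streams cumulatively. Derived per
draw: growth rates λ_t and their geometric mean, poison-free survival
φ*_a = φ + (1−φ)m_a, and the proportional reduction Δ_a = 1 − φ/φ*_a.
The perturbation module builds the pre-breeding matrix from
(φ*_a, Δ_a, f, γ, β₂), computes λ, sensitivities/elasticities of cells
and vital rates (exact chain rule), break-even poisoning levels, and
the λ-surface grids. See `docs/methods.md` for assumptions and
numerical choices.

## Worked example

Deterministic perturbation analysis at the full-model posterior means
(φ = 0.808, m = (0.428, 0.764, 0.764), f = 1.825, γ = 0.631):

```sh
$ kiteipm perturb --out out/
lambda = 1.0816 (8.2% per year)
break-even juv: delta = 0.447 (survival 0.492)
break-even 1y: delta = 0.484 (survival 0.492)
break-even 2my: delta = 0.252 (survival 0.714)
```

Reading: at current poisoning pressure the population still grows 8.2 %
per year, but poisoning already lowers adult survival by ~15 % (9 % for
juveniles); if the proportional reduction in the 2+ class deepened from
0.15 to 0.25 (survival 0.71), growth would stall. Full tables (matrix,
eigenvectors, cell and vital-rate sensitivities/elasticities, λ-grids)
are written as CSV under `out/`.

End-to-end on synthetic data:

```sh
kiteipm simulate --seed 1 --out sim/           # four CSV streams + truth.json
kiteipm fit --config config.yaml --variant ipm2 --out fit/
kiteipm project --config config.yaml --horizon 3 --out proj/
```

where `config.yaml` points at the four files and sets the MCMC budget:

```yaml
data:
  counts: sim/counts.csv
  productivity: sim/productivity.csv
  histories: sim/histories.csv
  recoveries: sim/recoveries.csv
mcmc: {chains: 3, iterations: 50000, burn_in: 25000, thin: 5, seed: 7}
```

`fit/posterior_summary.csv` lists mean, sd, central 95 % credible
interval and split-R̂ per parameter; `derived_quantities.csv` adds
λ̄, φ*_a and Δ_a.

## Acceptance script

`scripts/acceptance.py` recomputes the deterministic headline numbers
from scratch — it builds the projection matrix at the posterior-mean
vital rates and measures annual growth, the poison-free survival
back-transformations, and the three break-even reductions by bisection:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
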