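# spatburst

Spatial stochastic modelling and inference of bursty nuclear transcription.

Nascent mRNA is transcribed at a fixed gene site inside the nucleus, diffuses
through the nuclear interior, and is either degraded or exported at the
nuclear envelope.  Single-molecule imaging (smFISH and relatives) resolves the
positions of individual transcripts per cell — information that count-based
models of gene expression discard.  `spatburst` implements a tractable
spatial stochastic model for these data and the machinery to fit it:

* a **telegraph (two-state) promoter** switching between an "on" rate λ and an
  "off" rate λ_off at rates α (off→on) and β (on→off);
* transcripts performing **Brownian motion** with diffusivity D on a domain
  Ω (an interval [−R, R] in 1D, or a polygon with spatially varying D(x) in
  2D), **degraded** at rate γ and **exported** at the boundary with rate
  parameter κ (κ = 0 reflecting, κ = ∞ absorbing, finite κ a Robin condition
  homogenizing nuclear pores).

Steady-state observations of this model form a **Cox point process**: the
transcript positions x₁,…,xₙ are a Poisson process whose intensity u(x)
solves a stochastically switching reaction–diffusion PDE

∂ₜu = D∇²u − γu + Λ(t)·δ(x − z),  Λ(t) ∈ {λ_off, λ}.

The package provides, for this process:

| layer | what it computes |
| --- | --- |
| `spatburst.simulate` | exact-promoter / Euler–Maruyama particle simulator (1D & 2D), the ground truth for everything else |
| `spatburst.analytic` | closed-form mean intensity ⟨u(x)⟩, scale factors S and S_κ, mean counts ⟨n⟩ = λρS/γ, the eigenmode double series for var(n), spatial and non-spatial Fano factors |
| `spatburst.distributions` | the Poisson-beta count law with spatially rescaled parameters (λ̃, α̃, β̃) = S·(λ, α, β)/γ, plus Jensen–Shannon comparison tools |
| `spatburst.pde` | steady-state finite-difference solvers (1D oracle; 2D heterogeneous-D domains) and the generalized scale factor S = γ∫⟨u⟩/λ_p |
| `spatburst.inference` | approximate Cox-process likelihood L ≈ p(n)·∏ᵢ p(xᵢ), Nelder–Mead MLE over θ = (λ, γ, α, β, κ), profile-likelihood identifiability |
| `spatburst.synthdata` | seeded generators: heterogeneous cell populations, random 2D domains, parameter-sweep tables |

The central quantity is the dimensionless **scale factor** S ∈ [0, 1]
(absorbing boundary: S = 1 − cosh(z√(γ/D))·sech(R√(γ/D))), the probability
that a transcript is degraded inside the nucleus rather than exported.  It
absorbs all geometry: the non-spatial telegraph results apply after the
rescaling (λ, α, β) → S·(λ, α, β)/γ, which makes the full count
distribution approximately Poisson-beta even for heterogeneous 2D domains,
and underpins a per-cell likelihood cheap enough for population-level
inference.

## Worked example

```python
import numpy as np
from spatburst import (
    Domain1D, ModelParams, SimConfig, empirical_counts, jensen_shannon,
    mean_count, poisson_beta_pmf, sample_counts, scale_factor_S,
    spatial_rescale, var_count,
)

p = ModelParams(lam=10, alpha=1, beta=1, gamma=1, D=1, z=0.5)
dom = Domain1D(R=1.0, boundary="absorbing")

S = scale_factor_S(p, dom)
print(f"S = {S:.4f}, <n> = {mean_count(p, dom):.4f}, var(n) = {var_count(p, dom):.4f}")

counts = sample_counts(p, dom, 4000, SimConfig(seed=1))
print(f"simulated mean {counts.mean():.3f}, var {counts.var(ddof=1):.3f}")

pred = poisson_beta_pmf(spatial_rescale(p, S))
print(f"JS divergence (bits): {jensen_shannon(pred, empirical_counts(counts)):.5f}")
```

Output:

```
S = 0.2692, <n> = 1.3462, var(n) = 2.5025
simulated mean 1.354, var 2.478
JS divergence (bits): 0.00046
```

With the gene site at z = 0.5 (half-way to the boundary) only ~27% of
transcripts are degraded before being exported, so the mean count drops to
1.35 from the non-spatial value λρ/γ = 5, and the count distribution is
super-Poissonian (Fano ≈ 1.86).  The particle simulation reproduces both
moments within Monte-Carlo error, and the rescaled Poisson-beta pmf matches
the empirical count histogram to a Jensen–Shannon divergence of 5·10⁻⁴ bits.

Fitting kinetics to a heterogeneous synthetic population:

```python
from spatburst import PopulationSpec, generate_population, fit_mle, profile_likelihood

patterns, manifest = generate_population(PopulationSpec(M=500, seed=11))
fit = fit_mle(patterns, {"lam": 10, "gamma": 0.5, "alpha": 0.5, "beta": 1, "kappa": 2},
              D_known=1.0)
print({k: round(v, 2) for k, v in fit.theta_hat.items()})
# {'lam': 19.1, 'gamma': 0.86, 'alpha': 0.95, 'beta': 1.76, 'kappa': 7.35}
grid, chi = profile_likelihood(patterns, fit, "gamma")   # identifiability curve
```

(the generating truth is λ=20, γ=1, α=1, β=2, κ=5 with D=1 known).

A thin CLI wraps the same workflow: `spatburst simulate config.yaml`,
`spatburst fit patterns.csv geometry.csv`, `spatburst profile ... gamma`.

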