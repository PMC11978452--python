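# Methods

## Model

`spatburst` describes nuclear mRNA as a spatial birth–death–diffusion
process with a bursty source.  A two-state promoter at a fixed site z ∈ Ω
switches between transcription rates λ_off and λ at rates α (off→on) and β
(on→off); each transcript performs Brownian motion with diffusivity D,
is degraded at rate γ anywhere, and is exported when it reaches the
boundary, with export kinetics encoded by a single rate parameter κ
(Robin condition D∇u·n = −κu; κ = 0 reflecting, κ → ∞ absorbing).  Only
the steady state is considered: snapshots are assumed to be taken long
after any cell-cycle transient, and the gene site is treated as immobile.

Conditioned on the promoter path, transcripts are independent, so the
observed positions form a Poisson process whose intensity solves a
switching reaction–diffusion PDE; unconditionally the observations are a
Cox process.  Everything in the package is organized around consequences
of that representation.

Units are unconstrained but must be consistent; the documentation uses µm
and seconds, the scales of nuclear mRNA imaging (D ~ 0.03–0.1 µm²/s,
nuclear radius a few µm, degradation and export on comparable timescales).

## Scale factor and moment layer (1D, Ω = [−R, R])

With λ_off = 0, the steady-state mean intensity ⟨u(x)⟩ solves a two-point
boundary-value problem with a point source of strength λρ at z, where
ρ = α/(α+β) is the stationary on-fraction.  Closed forms are implemented
for the absorbing and Robin cases; all hyperbolic expressions are
rewritten as ratios of exponentials with non-positive arguments, so they
are overflow-safe for arbitrarily large √(γ/D)·R (no asymptotic
switch-over is needed).

Integrating ⟨u⟩ gives ⟨n⟩ = (λρ/γ)·S with the dimensionless scale factor

    S = 1 − cosh(z√(γ/D)) · sech(R√(γ/D))        (absorbing),

and its Robin generalization S_κ.  S is the probability that a transcript
is degraded inside the domain rather than exported: it increases with γ
and R and decreases with D, |z| and κ.  Consequently S_κ is monotone
**decreasing** in κ, with S₀ = 1 (no export — the non-spatial mean λρ/γ
is recovered, by mass balance) and S_∞ = S.  The Robin closed forms were
re-derived from the boundary-value problem and are cross-checked in the
test suite against an independent finite-difference solve, against
numerical quadrature of the Robin mean intensity, and against both κ
limits.

The super-Poissonian part of the count variance,
var(n) − ⟨n⟩ = ∫∫ Cov(u(x), u(y)) dx dy, is evaluated as a double series
over the odd sine eigenmodes of the absorbing interval.  Writing
r_m = γ + π²Dm²/(4R²) for the mode decay rates and ω = α + β, the (k, l)
term is

    ψ · (r_k + r_l + 2ω) / [(r_k + ω)(r_l + ω)(r_k + r_l)]
      · 16 sin(πk(R+z)/2R) sin(πl(R+z)/2R) / (π² k l),   k, l odd,

with ψ = λ²αβ/(α+β)² the variance of the dichotomous production rate.
Every term is positive with this (positive-rate) convention.  The sum is
truncated by doubling the square truncation order until the change falls
below a relative tolerance (default 1e−10, floored at the double-precision
rounding noise of the ~10⁷-term sum); terms decay like 1/(k²l²(k²+l²)), so
shell doubling converges quickly.

## Poisson-beta count approximation

The non-spatial telegraph model has a Poisson-beta stationary count law.
The package's central approximation is that the spatial model does too,
after absorbing the geometry into S:

    λ̃ = Sλ/γ,  α̃ = Sα/γ,  β̃ = Sβ/γ,

(the division by γ reflects that only rate ratios are identifiable at
steady state).  This choice reproduces ⟨n⟩ exactly and the variance almost
exactly: across the default sweeps the exact Poisson-beta variance of the
rescaled parameters tracks the eigenmode series to within ~4–5%, with the
relative gap widening (to ~6–8%) only as z → R where both variances
vanish.  The full pmf agreement is quantified by base-2 Jensen–Shannon
divergence against simulation; the acceptance script reports values of
order 10⁻³ at 5,000 samples.  Whether the spatial count law is *exactly*
Poisson-beta is unknown; the package treats it as an approximation and
always exposes the simulator as ground truth.

Two independent pmf routes are implemented: (i) a stable confluent
hypergeometric evaluation — the ₁F₁(α̃+n, α̃+β̃+n; −λ̃) form is
Kummer-transformed so that every series term is positive, with log-space
Pochhammer ratios and renormalization against overflow; (ii) Gauss–Jacobi
quadrature of the Beta mixture integral, whose weight absorbs the
endpoint singularities that appear when the rescaled shapes fall below 1
(plain Gauss–Legendre converges too slowly there).  The routes agree to
1e−10 per entry in the tests; route (ii) is also the automatic fallback.
The truncation bound defaults to the smallest n with Poisson(λ̃)-envelope
tail mass below 1e−10 (valid since the mixture is dominated by its largest
rate); truncated mass is carried explicitly as `tail_mass`.

Jensen–Shannon divergence is computed in bits (base 2) so that it lies in
[0, 1]; it is the divergence, not its square root (the "distance").

## Particle simulator

The simulator is hybrid and exact where exactness is cheap:

* promoter paths are event-driven (exponential holding times, stationary
  initial state) — no discretization;
* birth times are drawn exactly per constant-rate stretch (Poisson counts,
  uniform placement) and each particle carries an Exponential(γ) lifetime
  drawn at birth;
* diffusion is Euler–Maruyama with default step
  dt = min(1/(100γ), R²/(1000D)), additionally capped for Robin
  boundaries so that the export probability per boundary contact,
  P = κ√(π·dt/D), stays ≤ 0.15.

Boundary handling: absorbing boundaries remove crossing particles and
additionally remove non-crossing particles with the Brownian-bridge
first-passage probability exp(−(R−x₀)(R−x₁)/(D·dt)), which suppresses the
O(√dt) bias of naive crossing detection; Robin boundaries export a
contacting particle with probability κ√(π·dt/D) (the partially reflected
Brownian motion construction) and mirror-reflect it otherwise; reflecting
boundaries always mirror.  The Robin scheme's residual O(√dt) bias is at
the percent level for moment estimates at the default cap; datasets
generated for position-resolved likelihood work are more sensitive, so the
population generator tightens the cap to P ≤ 0.125 of its own accord (at
that setting the residual bias in refitted parameters is below the
sampling error of populations up to M ~ 10³ cells).

Ensembles of independent cells are propagated together in flat arrays
(positions, owning-cell index, death time), so thousands of stationary
snapshots cost one sweep of the time grid.  Particles whose lifetime ends
before the next retained snapshot are never simulated — an exact pruning,
since particles do not interact.  Burn-in defaults to ten multiples of the
slowest relaxation time max(1/γ, R²/D, 1/(α+β)) starting from an empty
domain; when several snapshots per cell are harvested they are spaced
three correlation times apart (residual correlation ~e⁻³, noted where
standard errors are computed from such samples).  In 2D, increments use
√(2D(x)dt) with D evaluated at the pre-step position (Itô convention), and
the absorbing polygon boundary is enforced by containment tests without a
bridge correction, so 2D count means carry a small positive O(√dt) bias
(~3% at defaults) — adequate for the distribution-level comparisons it
serves.  Everything is a pure function of the seed.

## Steady-state PDE layer (2D, heterogeneous D(x))

For a 2D domain with spatially varying diffusivity under the Itô
convention, the mean intensity solves ∇²[D(x)u] − γu + λ_p δ(x−z) = 0 with
u = 0 on the boundary.  Substituting w = D(x)u turns this into a standard
Poisson-type problem ∇²w − (γ/D(x))w = −λ_p δ, discretized with the
five-point stencil on a regular grid masked to the polygon (second order
in the interior; the staircase boundary dominates the error for rough
polygons).  The point source is spread over the four surrounding nodes
with bilinear weights, conserving unit mass; since the downstream quantity
is the integral functional S = γ·∫u/λ_p, the result is insensitive to the
mollification width (tested by self-convergence under mesh refinement).
Quadrature uses trapezoidal edge weights, which matters only for Neumann
edges.  A `neumann_y` option turns the horizontal sides of a rectangular
domain reflecting: integrating the discrete equations over y then
reproduces the 1D problem exactly, giving a degenerate-strip validation
against the closed forms (observed convergence order ≈ 2).  Robin
conditions in 2D are out of scope for this solver; the 2D demonstrations
are purely absorbing.

Random test geometries are star-convex polygons
r(θ) = R₀(1 + Σₖ aₖcos(kθ+φₖ)) with harmonic amplitudes of scale
`roughness` (invalid draws are regenerated), and diffusivity fields are
sums of Gaussian bumps squashed smoothly into a positive range.

## Approximate likelihood and inference

The exact Cox-process likelihood integrates over all intensity
realizations and is intractable.  The package uses the factorization that
is exact for deterministic intensities:

    L(θ; x₁..xₙ) ≈ p_θ(n) · ∏ᵢ ⟨u(xᵢ)⟩ / ∫⟨u⟩,

a mean-field approximation that ignores count–position correlations.
p_θ(n) is the Poisson-beta law with the per-cell S_κ(Rᵢ, zᵢ); the
positional density is the normalized Robin mean intensity (its λρ
prefactor cancels, so positions inform only γ, D, κ and the geometry).
For β = 0 (constitutive limit) the intensity is deterministic and the
expression is the exact Poisson point-process likelihood; the count term
then switches to the Poisson pmf explicitly.

Populations are heterogeneous: each cell carries its own (Rᵢ, zᵢ) while
kinetics are shared, and D is assumed known (measurable by live-cell
tracking).  Likelihood evaluation is vectorized across cells (one
fixed-point Kummer recursion over all cells simultaneously; all positional
terms in one array pass), costing ~1 ms per evaluation at M = 100.

Maximization is Nelder–Mead over log-parameters (all five parameters are
positive rates of different magnitudes; the log transform enforces
positivity without explicit bounds).  Positions within 1e−9·R of an
absorbing boundary are clamped inward, since simulated snapshots can land
arbitrarily close to the boundary where the density vanishes.

Identifiability is diagnosed by profile likelihoods: each parameter is
fixed on a grid (default 21 log-spaced points spanning ×/÷4 around its
MLE) and the other four are re-optimized, warm-starting outward from the
MLE.  The reported curve is χ(θᵢ) = log PL(θᵢ) − log L(θ̂) and the
confidence region is {χ ≥ −χ²₀.₉₅,₄/2} — the *simultaneous* convention
with four degrees of freedom (the number of re-optimized nuisance
parameters), deliberately wider than the common 1-df pointwise interval.
Profile optimizations use looser simplex tolerances (fatol 5e−3) than the
MLE itself; χ values are therefore meaningful to ~0.01, far below the
4.74 threshold.

Two structural facts are encoded as tests rather than assumptions: counts
alone leave a two-parameter flat manifold (any (γ, κ) change can be
absorbed into (λ, α, β) without moving the Poisson-beta parameters of a
shared geometry), while the positional terms break that degeneracy; and
the approximate MLE on telegraph data is somewhat biased (true parameters
tend to sit toward one end of the confidence region), so recovery tests
assert coverage of the simultaneous region, not unbiasedness.  In the
exact β = 0 sub-model the bias of the (λ, γ, κ) estimates shrinks as M
grows, which the tests check at M = 50/200/800.

## Synthetic study populations

The default heterogeneous population mimics a realistic smFISH cohort:
M = 500 cells, Rᵢ ~ Uniform(0.8, 1.2), zᵢ | Rᵢ ~ Uniform(−0.8Rᵢ, 0.8Rᵢ),
shared kinetics θ = (λ=20, γ=1, α=1, β=2, κ=5) with D = 1 treated as
known.  These defaults are package choices (chosen once to give a few
transcripts per cell, clearly super-Poissonian counts, and comparable
degradation and export fluxes) and are recorded in the run manifest, so
every dataset is regenerable bitwise from (spec, seed).  The generator
emulates steady-state snapshots of independent cells; it does **not**
emulate cell-cycle transients, segmentation error, localization noise, or
z-projection artifacts of real imaging, so passing recovery tests show
correctness of the inference machinery under the model, not robustness to
real-data nuisances.

## Problem sizes in the shipped tests

The test suite validates each claim at sizes chosen to keep the full run
at a few minutes while leaving Monte-Carlo bands meaningful: 5,000 count
samples per gene-site location for distributional comparisons; 2,200–3,000
cells per point for mean/variance sweeps (3–3.5 standard-error bands,
with variance standard errors computed from fourth moments); M = 300
cells with 11-point profile grids for the five-parameter recovery; and
M = 50/200/800 with two replicates for the constitutive consistency
check.  Where several bins or sweep points are tested jointly, per-bin
thresholds are Bonferroni-widened so the family-wise false-alarm rate
stays at the percent level.

## Known limitations

* Variance series and Poisson-beta rescaling require λ_off = 0; calling
  them with λ_off > 0 raises rather than silently approximating.  The mean
  layer supports λ_off > 0 through the weighted production rate.
* No closed-form variance exists here for finite κ; finite-κ variances
  come from the Poisson-beta approximation or simulation.
* The 2D solver is absorbing-only, isotropic, on a fixed grid (no
  adaptivity, no 3D).
* The likelihood is a mean-field approximation away from β = 0; its
  estimator bias, though small relative to confidence regions at
  M ≤ 500, does not vanish with M.
* Robin-boundary simulation bias is O(√dt); parameter-sensitive uses
  should tighten the step (see the simulator section).
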