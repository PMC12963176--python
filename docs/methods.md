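# Methods

## Model

The landscape is a periodic square `[0, L)²` holding `N` vegetation sites
drawn uniformly at random (seeded).  Each site is in one of four states —
forest (F), grass (G), burning (B), ash (A) — and follows a continuous-time
Markov jump process whose rates combine spontaneous transitions (mortality
`μ`, quenching `q`, regrowth `γ`) with spatial interactions mediated by
Gaussian kernels: forest seeding (`φ_G`, `φ_A` acting on the forest field
through `W_F`), fire spread (`β_F`, `β_G` acting on the burning field
through `W_B`), and percolation-like ignition cascades (sigmoids `Φ_F`,
`Φ_G` of the grass field through `W_G`).  Kernels carry the continuum
normalisation `1/(2πσ²)`, so the local fields `w_X = (1/N) Σ_j W_X 1{X_j=X}`
estimate local cover fractions; the focal site is excluded from its own
sums (a site's flammability depends on its neighbourhood, not itself).

Two deterministic companions are implemented: the nonlocal
integro-differential (IDE) system for the cover densities, in which the
flammability sigmoids act on the `W_G`-smoothed grass field — the only
reading under which spatially uniform data reduce *exactly* to the third
companion, the well-mixed ODE system on the 3-simplex.

### Assumptions

- Sites are fixed in space; only their states change.  Uniform site
  placement models a homogeneous domain.
- Kernels are isotropic Gaussians evaluated at minimal-image (torus)
  distances; wrap-around images beyond the principal one are neglected,
  which is accurate to < 1e-7 for `σ ≤ L/8` (an exact toroidal summation is
  available for wider kernels).
- Ash is a transient refractory state: recently burned land that cannot
  immediately re-burn and regrows grass at rate `γ`.
- Burning sites quench spontaneously; fire permanence is not modelled.

## Parameters

All rates are per year; a site spacing of about 1 m sets the scale.  The
defaults encode three levels of timescale separation,
`β_G, β_F, q ≫ γ ≫ φ_G, φ_A, μ, f0, g0`:

| parameter | default | meaning |
|---|---|---|
| `beta_G`, `beta_F` | 1e5, 1e4 | fire-spread magnitude over grass / forest |
| `q` | 1e4 | quenching (burn duration of hours; estimates down to ~1e3 appear in the source literature for longer burns — the order of magnitude is uncertain) |
| `gamma` | 1e2 | grass regrowth from ash (months) |
| `phi_G`, `phi_A` | 1 | forest seeding into grass / ash (years–decade) |
| `mu` | 1e-2 | background tree mortality (~century) |
| `f0, g0` / `f1, g1` | 1e-2 / 1e-1 | ignition floor / ceiling of the flammability sigmoids |
| `theta_F = theta_G` | 0.6 | percolation threshold of fuel connectivity (square-lattice site percolation) |
| `s_F = s_G` | 0.05 | sigmoid width (smooth step) |
| `sigma_F/B/G` | 5·L/√N | kernel widths, **in domain-length units**; `sigma_from_spacings` converts from mean-spacing units |

Two reference sets are used throughout tests and examples: a *partially
timescale-separated* set (`β_G=50, β_F=10, q=30, γ=10, φ=1, μ=0.01,
f0=g0=0.01, f1=0.5, g1=1`) that keeps continuation and settling cheap, and a
*fully separated* set (`β_G=5e4, β_F=1e4, q=2e4, γ=500, f1=0.05, g1=0.1`)
for simulation studies.

## Numerical methods

**Stochastic simulation.**  The simulator is an exact direct-method SSA:
exponential waiting times in the total rate, event selection proportional to
per-site rates via a Fenwick tree (O(log N)), and O(neighbourhood) rate
updates after each event.  Neighbour lists truncate each Gaussian at 4σ
(relative mass error < 4e-4, applied consistently in bookkeeping and in
`site_rates`, so cached fields agree with recomputation to < 1e-10; fields
and the tree are additionally rebuilt from scratch every 2²³ events to bound
floating-point drift).  One seeded generator drives each run; identical
seeds give bit-identical trajectories.  Cover fractions are recorded on a
fixed grid plus the horizon; an absorbing landscape pads the remaining
records.  With uniform kernels every site in a state class shares one rate,
so the run switches to an equivalent (exact) count-based SSA over the four
state counts — this is the law-of-large-numbers configuration used for
ODE-consistency checks.

**ODE integration and settling.**  Rates span seven orders of magnitude, so
all integration uses stiff-capable LSODA with the analytic reduced Jacobian;
three components are integrated and the fourth closed by conservation.
"Settled" means max |rhs| < 1e-8 /yr, reached by doubling the horizon from
50 yr (cap 1e4 yr) and then polishing the algebraic system by Newton in the
reduced (F, G, B) coordinates; trajectories that collapse onto the
forest-free boundary are polished within the GBA subsystem so forest stays
exactly zero.

**Steady states and bifurcations.**  The GBA root is bracketed on
`(0, min(1, q/β_G))` and bisected to 1e-12 (uniqueness follows from
monotonicity of the two sides of the balance).  Invasion stability is the
sign of the top-left entry of the block-triangular linearisation at `F = 0`;
branch points are its zeros, refined by Brent's method.  Branches of forest
equilibria are traced by pseudo-arclength continuation (secant tangent,
augmented Newton, adaptive step halving) — chosen over natural-parameter
continuation because it walks through folds without switching variables.
Stability is classified from the reduced Jacobian's eigenvalues; a leading
real part within 1e-8 of zero is reported as "marginal", never silently
classified.  Fold (LP) labels come from sign reversals of the parameter
tangent; transcritical (BP) labels from invasion-eigenvalue zeros and from
forest-branch crossings of `F = 0`.  Non-degeneracy can be certified via
`transcritical_curvature` (finite differences of the equilibrium burning
response `B̄(F)`).

The small-`g1` expansion of the branch-point locus
`(φ−μ̃)/(φ+β_F)`, `μ̃ = μ + f1`, assumes the saturated-flammability regime
`Ḡ > θ + 2s`; its checks therefore run with lowered thresholds (θ = 0.2,
s = 0.015) where the assumption holds and the measured error contracts by
one power of `g1` per order (fitted slopes ≈ 1, 2, 3).  Closed-form linear
asymptotics of the forest branch in the mortality rate are **not** provided
(`mu_asymptotics` raises); `fit_linear_regimes` fits the near-`F=0` and
near-`F=1` linear regimes of a continued branch empirically instead.

**Field equations.**  The IDE system is discretised on an n×n torus mesh
(default n = 128 for L = 1, σ = 0.05, i.e. ≥ 6 cells per kernel width); the
convolutions are circular, via FFT, with the kernel sampled at minimal-image
distances and renormalised to unit discrete mass so constants are exact
fixed points.  Method-of-lines integration closes A by conservation; uniform
initial data reproduce the ODE trajectory to integrator tolerance.

## Computed reference values

For the partially separated set the package computes (and
`scripts/acceptance.py` reproduces): GBA root `(Ḡ, B̄, Ā) =
(0.5649, 0.1088, 0.3263)` with invasion eigenvalue −0.379 /yr; transcritical
branch point in the regrowth rate at γ = 6.199 /yr; forest-seeding branch
point at φ = 1.4251 /yr with a fold at φ = 0.117, hence a bistable seeding
window (0.117, 1.425); and a settled low-forest onset that jumps from forest
exclusion to F ≈ 0.98 at the first grid value above the branch point
(φ = 1.45 on a 0.05 grid).  These values are mutually consistent: the onset
jump, the sign of the invasion eigenvalue at φ = 1 and the located branch
points all describe the same stability exchange, and each is cross-checked
by direct stiff integration.

## What the synthetic setups show — and what they do not

The canonical fixtures (`make_fixture`) generate the study conditions
programmatically: all-grass landscapes at fire-timescale rates, a 40%
randomly scattered forest landscape (N = 2000, φ = 1.5, σ_B = 0.03), and
the low-forest mean-field onset protocol.  Passing tests demonstrate
internal correctness (exact SSA bookkeeping, subsystem consistency,
forward invariance, convergence of expansions) and the headline
phenomenology: spatial bistability of forest and grass-fire attractors, and
fire-front blocking by dense forest.  They do not calibrate the model to any
real landscape: site placement is homogeneous, kernels isotropic, rainfall
seasonality, herbivory and tree life stages are absent, and rates are
order-of-magnitude estimates.

A caution for mean-field comparisons: the grassland (GBA) equilibrium pins
`β_G·Ḡ` just below `q`, so the fire mode is self-organised near criticality.
At timescale-separated rates and N ≈ 2000 individual stochastic runs make
O(1) excursions (recurrent large fires and slow fuel rebuilds) and ensemble
means genuinely depart from the ODE on fire timescales; this is a real
finite-size phenomenon of the model, not a numerical artefact.
Law-of-large-numbers agreement is therefore verified in subcritical regimes
(e.g. forest-dominated landscapes), where deviations shrink monotonically
with N, with a one-site (1/N) resolution allowance for components extinct
in every replicate.

## Known limitations

- Natural-parameter output of `continuation_1d` covers the requested range
  with adaptive arclength steps; disconnected equilibrium branches (isolas)
  that never approach the seed or the forest-free boundary would be missed.
- Two-parameter bifurcation surfaces, Hopf detection and normal-form
  coefficients are out of scope; neutral-saddle points are not separately
  labelled.
- The SSA cost grows with fire activity (each burning event touches ~πr²N
  neighbours at truncation radius r = 4σ_B); landscapes much beyond
  N ~ 10⁴ at fire-timescale rates call for coarser kernels or shorter
  horizons.
- Heavy-tailed or anisotropic kernels are accommodated by the pluggable
  kernel interface but are untested.
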