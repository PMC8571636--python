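# Methods

`stresscomm` simulates how multiple simultaneous environmental
stressors reshape competitive communities, separating two components of
stressor action that usually covary: how many stressors act (stressor
richness, *s*) and how much total damage they do (total stressor
intensity, TSI). The central device is an intensity-fixing rescaling of
the stressor-effect matrix that lets richness vary while TSI stays
constant.

## Stressor algebra

Stressors are press perturbations: each stressor *l* multiplies the
focal growth trait θᵢ of species *i* by an effect εᵢₗ ∈ (0, 1], and is
not itself affected by the populations. With *n* species and *s*
stressors the effects form a matrix **E**. Without interactions the
stressed trait is θᵢ = θᵢ,₀ · ∏ₗ εᵢₗ, i.e. additive in log space.
Pairwise trait-level interactions enter through a tensor η:

log θᵢ = log θᵢ,₀ + Σₗ log εᵢₗ + Σ_{l₁} Σ_{l₂} log εᵢₗ₁ · log εᵢₗ₂ · ηᵢₗ₁ₗ₂

with ηᵢₗₗ = 0 (a stressor does not interact with itself). Because the
logs of effects are negative, η > 0 is antagonistic (the joint effect
is milder than additive) and η < 0 synergistic. Two conventions here
are genuinely open and are implemented as documented defaults:

* **Log base in the interaction term.** Base 10 (the independent part
  is a pure product, so the base only matters when η ≠ 0). A
  `log_base` argument exposes the choice.
* **Ordered vs unordered pairs.** The double sum runs over both orders,
  so a symmetric η effectively weighs each unordered pair twice;
  `ordered_pairs=False` counts each pair once.

**Total stressor intensity** is TSI = 1 − ∏ᵢ∏ₗ εᵢₗ (computed in log
space), so stronger overall stress approaches 1. Fixing TSI at a target
uses the power transform ε′ᵢₗ = εᵢₗᵏ with
k = log d / log ∏ᵢ∏ₗ εᵢₗ where d = 1 − TSI. This preserves the rank
order of effects and the proportional pattern of who is hit by what,
while pinning the grand product at d exactly (enforced to 1e−10). The
transform is undefined when every entry is 1; that degenerate input
raises.

**SCV**, the stressor coefficient of variation, is the coefficient of
variation of the row products of **E** — the per-species combined
effects. It uses the sample (n−1) standard deviation. In the pipeline
SCV is computed on the matrix the species actually experience, i.e. the
rescaled **E** when TSI is fixed. Interaction tensors are sampled
before rescaling and are not themselves rescaled; the transform
operates on **E** only.

## Community models

Three competition models of increasing mechanism share one surface
(per-capita growth, focal trait θ, monoculture carrying capacity,
survivor subsetting). All dynamics are deterministic.

* **Lotka–Volterra**: dNᵢ/dt / Nᵢ = μᵢ − Σⱼ αᵢⱼ Nⱼ; θᵢ = μᵢ.
  Carrying capacity μᵢ/αᵢᵢ in closed form.
* **MacArthur consumer–resource**: per-capita growth
  Σₖ wᵢ cᵢₖ Rₖ − mᵢ with wᵢ species-specific (θᵢ = wᵢ). Resources renew
  logistically with linear (mass-action) uptake:
  dRₖ/dt = rₖ Rₖ (1 − Rₖ/Kₖ) − Σᵢ cᵢₖ Nᵢ Rₖ. This supply form is a
  design choice of this package; uptake is linear and resources are
  perfectly substitutable. The default resource count equals the
  species count (one dominant resource per species plus weaker shared
  uptake), which makes coexistence feasible.
* **Light-spectrum competition (Stomp-type)**: phytoplankton compete
  for wavelengths of light in a mixed water column of depth z;
  per-capita growth (ϕᵢ/z)∫₀ᶻ γᵢ(z′)dz′ − lᵢ with θᵢ = ϕᵢ, the
  photosynthetic efficiency. γᵢ(z) is the photon flux absorbed per
  capita by species i at depth z: the incident spectrum attenuated by
  Beer–Lambert through the whole community plus a background, weighted
  by species i's absorption spectrum, integrated over 400–700 nm.
  Spectra are Gaussian bumps with staggered peak wavelengths and a
  common width. Coexistence of more than four species on spectrum
  differentiation alone is not attainable, so this model runs only at
  four species. Integrals use the trapezoid rule on a 31-point
  wavelength grid and 51 depth points (both configurable); tests verify
  convergence by grid doubling to within 0.2%.

Carrying capacity for the resource and light models is the monoculture
equilibrium in the unstressed environment, found by bracketed scalar
root finding (per-capita growth is monotone decreasing in own
abundance in monoculture); it is cached per community by the pipeline.

## Equilibria and extinction

Equilibria are roots of the per-capita growth equations of the species
currently assumed present (plus per-capita resource balance for
MacArthur), solved by Broyden's quasi-Newton method with a Powell-hybrid
fallback and up to three perturbed restarts, to a residual max-norm of
1e−10 (200 iterations max). Stressed solves warm-start from the
unstressed equilibrium. For the light model the residual extends the
growth expression smoothly to negative abundances (with a clamped
exponent) so infeasible interior equilibria can be located.

A species is extinct when its equilibrium abundance falls below 1% of
its **unstressed** carrying capacity. Pruning iterates solve → remove
all below-threshold (including negative) species → re-solve, until the
survivor set is stable; the procedure is idempotent and terminates
because the survivor set strictly shrinks. Non-convergence is reported
in the solve report, never raised from the solver.

Stability of the located equilibrium is not checked by eigenvalues;
instead, tests cross-validate pruned Lotka–Volterra equilibria against
long-time ODE integration and exhaustive survivor-subset enumeration at
n ≤ 4, and MacArthur equilibria against stiff time integration. This is
a documented limitation: for the community sizes and parameter ranges
used here the integration endpoint and the pruned root have agreed in
all checked cases.

## Community generation

Focal traits are sampled log-normally, LogNormal(meanlog 0, sdlog
0.25), for all three models. The remaining ranges are this package's
own reconstructions of coexistence-friendly parameterizations and are
**not** taken from any published parameter table:

* Lotka–Volterra: αᵢᵢ = 1; αᵢⱼ ~ U(0.1, 0.9)/(n − 1). The 1/(n − 1)
  scaling keeps the expected total interspecific pressure on a species
  independent of richness; without it, communities of 8 or 16 species
  essentially never coexist.
* MacArthur: own-resource uptake U(0.6, 1.0), shared uptake
  U(0, 0.15), maintenance a U(0.2, 0.4) fraction of maximal intake at
  resource capacity, resource rate and capacity 1.
* Light model: peaks evenly spaced over 440–660 nm with ±10 nm jitter,
  width 40 nm, peak absorption 0.1, flat unit incident spectrum,
  background attenuation 0.05 m⁻¹, depth 10 m, losses a U(0.2, 0.4)
  fraction of the growth rate at zero abundance.

Candidate communities are screened: only those whose unstressed
equilibrium keeps every species at ≥ 1% of carrying capacity are
accepted. Rejection sampling uses one RNG stream per attempt (seed =
base seed + attempt index), so accepted communities are reproducible in
isolation from their recorded seeds. Non-convergent screens count as
rejections with a distinct status. Acceptance rates at four species are
high (≈ 1.0 for Lotka–Volterra and MacArthur, ≈ 0.5–0.7 for the light
model under the defaults above).

What the generator does *not* emulate: cotolerance (correlated
sensitivities across stressors), stressors that increase growth,
stressors acting on interaction coefficients, temporal stressor
variation, and trophic or mutualistic links. Passing tests therefore
speak to randomly-assembled competitive communities under press
disturbances, not to real assemblages with structured tolerance.

## Stressor sampling

Individual effects are i.i.d. Beta(α = 6.5, β = 0.25) — mild effects
near 1 are common, severe ones rare (mean ≈ 0.963). Interaction
coefficients are standard normal, symmetric in the stressor pair, zero
mean so interactions are additive on average.

## Metrics

* **Ecosystem function**: total surviving yield under stress over the
  unstressed total yield.
* **Persistence**: surviving-species count and its fraction of initial
  richness.
* **Compositional resistance**: Bray–Curtis similarity
  1 − Σ|x−y|/Σ(x+y). The pipeline feeds *relative* abundances, because
  a uniform down-scaling of every species (the typical fixed-TSI,
  high-richness outcome) is not a change of composition; on raw
  abundances the similarity saturates at the scaling factor and stops
  discriminating. The metric function itself accepts any non-negative
  vectors.
* **Biodiversity effects**: the additive partition ΔY = C + S with
  ΔRYᵢ = observedᵢ/monocultureᵢ − expected relative yield (1/n by
  default), C = n·mean(ΔRY)·mean(M), S = n·cov(ΔRY, M) (population
  covariance). Monoculture yields are computed under the same stressed
  traits (each species alone in the stressed environment); extinct
  species enter with observed yield zero but keep their monoculture
  yield. Both effects are reported scaled by ΔY, so they sum to 1; when
  |ΔY| is below 1e−12 relative to total monoculture yield the scaled
  shares are returned as missing. For the two-species symmetric case
  the scaled complementarity is defined as 1 − S/ΔY, which the scaling
  identity forces.

## Two-species closed forms

For a symmetric pair (α₁₂ = α₂₁ = α) with combined effects
e᷈ᵢ = ∏ₗ εᵢₗ, coexistence requires
α/α₁₁ < (μ₂e₂)/(μ₁e₁) < α₂₂/α. With unit intrinsic rates and
self-limitation, the stressed/pristine yield ratio is (e₁ + e₂)/2, and
with ρ = e₂/e₁,

S/ΔY = α (1/ρ − 2 + ρ) / (α − 1)², C/ΔY = 1 − S/ΔY.

These were rederived from the equilibrium solution of the pair and are
verified against the numeric partition to 1e−8 in tests. ρ is defined
from row products regardless of coexistence; the coexistence flag is
separate.

## Experiment pipeline and problem sizes

The full factorial design crosses TSI {10%, 50%, 90%, unfixed} ×
richness 1–20 × three models × initial richness {4, 8, 16} (the light
model only at 4) × interactions {absent, present} = 1120 cells at 1000
replicates each. Per-cell and per-replicate seeds derive from the base
seed through `numpy.random.SeedSequence`, so any replicate is
reproducible in isolation; replicates whose solve fails are replaced
with a fresh derived seed (up to 5 attempts, counts reported).
Aggregation reports per-cell means and empirical 10th/90th percentiles
(linear interpolation between order statistics); missing scaled
partition values are excluded with contributing counts reported.

The analysis scripts default to a scaled-down profile — Lotka–Volterra
and MacArthur at four species, richness {1, 2, 5, 10, 20}, TSI
{unfixed, 90%}, no interactions, 200 replicates — which resolves every
direction-of-effect result cleanly in about a minute on one core; the
full profile runs behind `--full` with per-cell files and resume
support. The direction tests use 200 replicates and richness
{1, 5, 10, 20}, and the sampling-only checks (ρ variance, SCV) use 1000
draws per setting.

The runnable interface is the numbered scripts under `analysis/`
(library functions cover everything they do); no separate console
entry point is shipped.

## Known limitations

* The sampling ranges are reconstructions; absolute metric levels
  (e.g. the exact persistence at a given richness) depend on them.
  Direction-of-effect results were robust across the ranges tried.
* No eigenvalue stability check on equilibria (see above).
* The light model's parameterization (flat incident spectrum, Gaussian
  absorption bumps) is a minimal spectral niche model, not a fit to
  measured pigment spectra.
* Scaled biodiversity effects are ratio statistics and can be
  heavy-tailed near ΔY ≈ 0; aggregate means should be read together
  with the reported percentile bands.
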