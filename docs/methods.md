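# Methods

## Model and assumptions

The population is well mixed (no network or spatial structure) and split
into three compartments: a constant inflexible core fraction σ_I and a
flexible remainder that is either peaceful (σ_P) or opponent (σ_O), with
σ_I + σ_P + σ_O = 1. Only two transitions exist — opponents recruit
peaceful agents (P→O at per-capita hazard β·σ_O) and inflexible contact
pacifies opponents (O→P at per-capita hazard α·σ_I). Nobody enters or
leaves the inflexible compartment, and the rates α and β are constant in
time. Mathematically this is an SIS-type contagion: eliminating σ_O via
the closure constraint leaves a scalar Riccati equation

dσ_P/dt = β (p₁ − σ_P)(p₂ − σ_P),  p₁ = 1 − σ_I,  p₂ = (α/β) σ_I.

Everything downstream — eigenvalues λ = ±β(p₁ − p₂), the critical core
fraction I_c = β/(α+β), the minimum engagement α* = (1/σ_I − 1)β, the
equilibrium pair selection — is exact algebra on those two roots.

## Parameters

| parameter | meaning | units | domain |
|---|---|---|---|
| σ_I | inflexible core fraction | dimensionless | [0, 1] |
| α | opponent→peaceful conversion rate per encounter | 1/time | ≥ 0 |
| β | peaceful→opponent conversion rate per encounter | 1/time | ≥ 0 |
| σ_O(0) | initial opponent fraction | dimensionless | [0, 1−σ_I] |

Time units are arbitrary: only the products αt, βt matter, so rates
set the clock. Scenario defaults are the nine built-in worked settings
(`fig1_fixtures()`), which span coexistence, extinction and a
near-fully-radicalized start; they are fixed reference inputs, not tuning
knobs.

## Numerical choices

- **Closed form vs integrator, dual route.** The analytic solution
  σ_P(t) = p₂ + (p₁−p₂)/(1 − A e^{β(p₁−p₂)t}) and an independent
  adaptive DOP853 integration (rtol 1e−12, atol 1e−14) are both
  implemented; tests enforce < 1e−8 sup-norm agreement on all nine
  reference scenarios, so each route checks the other.
- **Overflow guard.** For β(p₁−p₂)t > 700 the exponential branch is
  replaced by its analytic limit (the stable root), never evaluated.
- **Double root.** At p₁ = p₂ = p the generic formula degenerates; the
  implementation uses the Riccati power law σ_P(t) = p + u₀/(1 − β u₀ t)
  with u₀ = σ_P(0) − p. In the physical domain u₀ ≤ 0, so the
  denominator never vanishes for t ≥ 0. The form was verified against
  the integrator before adoption (tests keep verifying it).
- **Marginal regime.** σ_I = I_c exactly (within the module tolerance,
  default 1e−9, configurable) is reported as `marginal` and counted as
  thwarted: σ_O still reaches 0, but via a power-law rather than
  exponential approach.
- **β = 0 limit.** The second root is undefined; dynamics reduce to pure
  exponential decay of σ_O at rate α·σ_I. The report carries p₂ = NaN, a
  degeneracy flag, and σ_O_eq = 0.
- **Conservation.** σ_O(t) is always recomputed pointwise as
  1 − σ_I − σ_P(t), so closure holds to rounding (< 1e−12) by
  construction; the integrator state is the scalar σ_P only.
- **Horizon.** Default t_max = 20/|λ_stable| (512 output points), which
  resolves the relaxation to ~e⁻²⁰ ≈ 2e−9 of the initial deviation;
  `integrate_to_equilibrium` doubles the horizon until the residual
  |dσ_P/dt| falls below a requested tolerance (default 1e−10). In the
  marginal case λ = 0 and the fallback horizon is 20/(β|σ_P(0) − p|).

## Stochastic counterpart

The finite-N microdynamics is a continuous-time Markov chain over two
aggregate reaction channels, O→P at total rate α(n_I/N)n_O and P→O at
total rate β(n_O/N)n_P, simulated with the exact Gillespie direct
method. With these per-capita hazards the expected densities obey the
mean-field ODE with the *same* α, β, so the ABM converges on the ODE
equilibrium as N grows (tested as a decreasing-error trend over
N = 10², 10³, 10⁴, and as a 3/√N band at N = 10⁴). The chain absorbs at
n_O = 0 — at finite N extinction is always possible by fluctuation, and
in the thwarted regime it is certain. The event-scheduling scheme is a
design choice: the model specifies rates, not an updating scheme, and
the exact CTMC avoids the known sensitivity of discrete-time opinion
models to activation order. A discrete-time polling backend would be a
possible alternative; it is not implemented. Each replicate draws from a
child stream of `SeedSequence(seed)`, so runs are bit-reproducible given
(config, seed); the seed is mandatory in the config and echoed in every
summary.

## Radicalization indices and labels

ζ = σ_O/(1−σ_I) and η = σ_O/σ_I both recover σ_O (η·σ_I = ζ·(1−σ_I));
ζ is bounded in [0, 1], η is unbounded and reported as a flagged
infinity when σ_I = 0 (with ζ defined as 0 when σ_I = 1). The
qualitative labels in `interpret` use cutoffs ζ_low = 0.25,
ζ_high = 0.75, η_high = 1 — the last encodes "opponents outnumber the
core". These cutoffs are illustrative implementation defaults (the
underlying qualitative grid is stated only verbally in the literature),
are configurable, and never feed back into any computation. In the
middle ζ band the label falls back to the η criterion (alarming vs
contained).

## Phase diagrams

The thwarted/permanent classification depends on (α, β) only through
α/β, so grids live on (σ_I, α/β) with β = 1 internally; defaults are 99
points on σ_I ∈ [0.01, 0.99] × 100 log-spaced ratios on [0.01, 100],
resolving the boundary hyperbola α/β = 1/σ_I − 1 near σ_I → 0. Boundary
cells are flagged `marginal` so renderers can draw the curve. The CSV
grid is the tested artifact; the figure is cosmetic.

## What the tests do and do not show

All checks run on exact mean-field mathematics and its own stochastic
counterpart; the reference scenarios are parameter settings, not data.
Passing tests therefore demonstrate internal correctness — algebra,
integration, simulation and their mutual consistency — not that any real
population follows these dynamics. In particular the model assumes
perfect mixing, constant rates, a frozen core fraction and only three
behavioral states; real radicalization dynamics involve network
structure, time-varying engagement and demographic drift, all outside
scope (as is estimating α, β from observed data).

## Problem sizes

Deterministic runs use 512 output points per trajectory. Stochastic
validation uses N = 10⁴ with 32 replicates for the equilibrium and
absorption checks, and N ∈ {10², 10³, 10⁴} with 12–24 replicates for the
convergence trend — sizes at which the 1/√N fluctuation bands are tight
enough to discriminate while a full run stays in the seconds-to-minutes
range on one core.
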