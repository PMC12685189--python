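# Methods

## Model and assumptions

The system is a well-mixed chemostat coupled to a single homogeneous biofilm
compartment on the vessel wall. Six ordinary differential equations track
nutrient *S*, fluid and biofilm enzyme *E₁*, *E₂*, fluid and biofilm
cooperators *X₁*, *X₂*, and fluid cheaters *X₃* (equations in the README).
Assumptions worth making explicit:

- **Uptake** requires both nutrient and enzyme: F(S, E) = μSE/(K_S+S)
  vanishes when either is absent and is strictly increasing in both. The
  per-capita nutrient drain is F/γ, with γ the biomass yield.
- **Energy budget.** Cooperators split energy (1−Q) growth / Q
  quorum-sensing behaviours; enzyme output is ηQF per capita. Cheaters put
  everything into growth and produce nothing.
- **Biofilm capacities.** The biofilm holds at most Ê₂ enzyme and X̂₂ cells
  per area. Occupancy ratios M = E₂/Ê₂, W = X₂/X̂₂ split biofilm production
  into a retained part (1−M, 1−W) and a leaked part (M, W) that appears in
  the fluid. The ratios are deliberately **not clamped** at 1: when a pool
  overshoots its capacity the retention term goes negative, which *is* the
  overflow flux draining the excess back into the fluid. Clamping instead
  lets adhesion pump X₂ two orders of magnitude past capacity (the
  α/δ·X₁ inflow has nothing to balance it), which starves the fluid phase
  and destroys both the three-variant coexistence at the reference medians
  and the limit cycles in the growth-rate sweep. Adhesion itself is not
  modulated by occupancy.
- **Mass conservation across compartments.** Fluid quantities are per
  volume, biofilm quantities per area; δ converts area to volume units.
  Every boundary-crossing flux carries δ (biofilm→fluid) or 1/δ
  (fluid→biofilm), so the combined budgets X₁+δX₂ and E₁+δE₂ contain no
  exchange terms. Property tests assert this term by term.
- **Homogeneous biofilm.** No spatial structure, no within-biofilm cheater
  subpopulation; cheaters live only in the fluid.

## Numerical protocol

Integration uses LSODA (stiffness-switching) at rtol 2×10⁻¹⁰, atol 10⁻¹⁰,
on a unit-spaced output grid to t_end = 20,000 time units (10,000 for the
growth-rate sweeps, extrema over the trailing 2,500 points). Random
parameter draws span four orders of magnitude, so occasional stiffness is
expected; the tolerance pair keeps decaying variables accurate near zero.

**Epsilon floor.** Inside the derivative callback any enabled state variable
below machine epsilon (2.22×10⁻¹⁶) is reset to it, so near-extinct pools
cannot go negative and can regrow if conditions turn favourable. The floor
is applied only to variables *enabled* in the scenario: the cheater is
enabled iff X₃(0) > 0, the two biofilm pools iff α > 0, fluid cooperators
iff X₁(0) > 0, S and E₁ always. Two reasons. First, flooring a structurally
absent variable would seed it from nothing — a cooperator-only scenario
would be silently invaded by a phantom cheater growing out of the floor.
Second, the biofilm enzyme *must* be seeded by the floor: its production
term ηQF(S,E₂)X₂ is proportional to E₂ itself, so from E₂(0) = 0 the pool
can only start growing from the numerical floor once biofilm cells exist.
The floor is applied again to reported outputs, so stored trajectories are
never negative.

## Outcome classification

A finished run is labelled from the final concentrations of the enabled
bacterial variants. A variant *passes* if its final concentration is ≥ 0.01
and its share of the total population is ≥ 5% (both inclusive). Categories:
full coexistence (all pass), tragedy (all below 0.01), cheater exclusion /
competitive exclusion (exactly two pass *and* the failing variant is below
the 0.01 floor — i.e. actually driven out), and "other" (everything else,
including stable totals where a variant persists above the floor but holds
under 5%). Shares are computed in fluid-volume units by default (X₂ enters
as δ·X₂ so the three variants are commensurable); a `basis="raw"` switch
compares per-area and per-volume concentrations directly. Thresholds are
parameters, not constants.

## Sampling designs

The surveys draw log-uniformly (exp of a uniform on log bounds) over
[0.01, 2) for initial conditions, conversion factors, S⁰ and the biofilm
capacities, and over [0.001, 1) for the sloughing/adhesion rates; uniformly
over [0.1, 1) for D and Q (lower bound raised so near-neutral washouts
resolve within the horizon) and [1, 100) for μ. K_S is log-uniform on
[0.001, S⁰), re-coupled to the S⁰ drawn in the same simulation. Both biofilm
pools start empty. Four growth conditions toggle α and X₃(0) between drawn
and fixed-zero. One root seed spawns per-draw child streams, so draw *i* is
identical regardless of batch size and batches parallelize reproducibly.

**Cooperator-stable restricted design.** The invasion experiment needs a
region of parameter space where cooperator-only communities are always
stable. The packaged design (`data/cooperator_stable_ranges.yaml`, a derived
stand-in regenerable with `scripts/calibrate_ranges.py`) draws the eight
quantities the sensitivity analysis perturbs (K_S, μ, S⁰, α, β_X, δ, γ,
X₁(0)) from the inner quartile range of the fully stable subset of a
3,000-draw biofilm-cooperator survey, and pins every other quantity at the
reference stable-median values. Cooperator-only draws from this design
verify as 100% fully stable (the experiment re-checks this per batch and
aborts past a configurable failure fraction), so no further narrowing was
applied. Invasion then re-runs each verified draw with X₃(0) ~ log-uniform
[0.01, 2).

## Reference operating point

The deterministic scenario panel uses the median parameter values of the
fully stable three-variant ensemble (S⁰ = 0.76202, δ = 0.08377, η = 0.80704,
γ = 0.71445, Ê₂ = 0.19065, X̂₂ = 0.23565, β_E = 0.02042, β_X = 0.00699,
D = 0.41712, Q = 0.47026, μ = 68.07673, α = 0.11401) and initial state
S(0) = 0.14862, E₁(0) = 0.13806, X₁(0) = 0.27003, X₃(0) = 0.11655, with
empty biofilm pools. **K_S = 0.01** is this package's choice for the one
constant the median list does not pin down; it sits at the median of the
stable subsets our own surveys produce (≈ 0.009–0.015 across conditions) and
places the Hopf crossing of the sweep study at μ* ≈ 7.93, consistent with
the rest of the reference behaviour. The sweep study modifies two values
(Ê₂ = 0.13, S⁰ = 0.5) and scans μ.

## Equilibria, spectra, Hopf

Equilibria are located with a damped Newton solve (hybrid Powell, analytic
Jacobian) seeded from the endpoint of a long integration; convergence means
residual norm < 10⁻¹⁰ and a nonnegative root. Linearization uses central
finite differences (default relative step 10⁻⁷) cross-checked against the
hand-derived Jacobian to 10⁻⁶ relative to the matrix scale — entry-wise
10⁻⁶ is unattainable for ill-scaled draws where a near-singular Monod factor
puts entries of order 10⁴ beside order-1 ones. A μ sweep integrates each
grid point from the reference initial state, takes trailing-window extrema
(cycle iff max−min > 10⁻³ on a persisting variant), labels the regime
(washout / cheater exclusion / limit cycle / full coexistence), and attaches
the spectrum at the equilibrium reached from that endpoint — inside the
cycle band the root solve pulls in the enclosed focus, so one branch is
tracked across the transition. Hopf detection brackets a sign change of the
leading complex pair's real part (requiring nonzero imaginary part on both
sides, which rejects folds and the transcritical cheater-invasion point) and
bisects to |Δμ| < 10⁻³.

## What the generator emulates, and what it does not

The synthetic draws emulate the study design itself — independent
per-simulation parameter draws across biologically plausible ranges — not
any measured organism. Real chemostat communities have measurement noise,
demographic stochasticity, mutation (cheaters *arising*, not only being
introduced), and spatially structured biofilms none of which are modelled.
Passing tests therefore certify the deterministic model and its computation,
not predictions for any particular organism.

## Problem sizes and known limitations

The test suite runs every deterministic scenario at full length (20,000
time units) and the Monte Carlo studies scaled down: 2,000-draw invasion,
500-draw no-biofilm universality, 1,000-set well-posedness fuzzing at
t_end = 2,000, 10⁵-draw sampler-conformance checks, 12–15 point stability
grids. These sizes resolve fractions to a few percent; the rare-event
tragedy rate after invasion (≈ 5×10⁻⁴ at full scale) needs ≥ 5×10⁴ runs to
estimate and is only bounded (≤ 1%) at desk scale.

The cooperator-stable restricted design is derived by this package's own
calibration, so the invasion-outcome fractions depend on it: with the
packaged design, invasion of 2,000 verified-stable communities yields
roughly 41% full coexistence, 47% cheater exclusion, ~10% competitive
exclusion/other and < 1% tragedy. The split between coexistence and
exclusion is sensitive to exactly which quantities are drawn versus pinned
and to their ranges; the qualitative conclusions — invasion is almost always
absorbed or repelled, collapse is rare and confined to corners where the
biofilm cannot grow (low S⁰, low γ, high δ) — are robust across the designs
we tried.
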