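# Methods

## The model

`graftnet` couples two sub-models of early vein-graft arterialization over a
28-day follow-up (time in days everywhere; the 2-hour harvest is 1/12 day).

**Gene cluster networks (CN).** The transcriptional response is summarized by
five gene clusters, labeled A–E, whose mean expression trajectories G_i(t)
(relative [mRNA] units) obey a mutually interconnected linear system with a
scalar cubic time modulation:

    dG_k/dt = lambda(t) * sum_j A[j,k] (G_j - B_j),
    lambda(t) = C1 t^3 + C2 t^2 + C3 t + 1.

`A[j,k]` is the constant influence of cluster j on cluster k, `B` the
asymptote levels, and `lambda` shapes the early inflammatory excursion. The
same gene set is mapped into three separate networks — cell mitosis (MIT),
cell apoptosis (APOP), extracellular-matrix synthesis (ECM) — each with its
own 33 unknowns (25 couplings + 5 asymptotes + 3 modulation coefficients).
Because `lambda` is scalar, the exact solution is
`G(t) = B + expm(A^T Λ(t)) (G0 - B)` with `Λ = ∫lambda`; the public simulator
integrates the ODE adaptively (LSODA, rtol 1e-8) and the exact
eigendecomposition form serves as a fast batched evaluator inside the
calibration loop. The two routes are cross-checked in the test suite.

**Wall mechanics (DS).** The graft is a straight cylinder with lumen radius
R1 (baseline 1 mm) under Poiseuille flow, so wall shear is
`tau = 2 mu U_eff / R1` with `U_eff = flow_factor * U`. With mu = 3.2 cP and
a unit (1 m/s) centerline velocity the arterial baseline is tau0 = 6.4 Pa;
the ligated graft runs at `flow_factor = 0.1` (90% flow reduction). Only a
shear *deficit*, `Δτ⁻ = min(tau - tau0, 0)`, drives growth:

    dA_SMC/dt = -alpha1(t) Δτ⁻ A_SMC
    dA_ECM/dt = -alpha2(t) Δτ⁻ A_SMC      (A_ECM floored at 0)

where A_SMC and A_ECM are the cellular and matrix cross-sectional areas of
the intima (mm^2). New intima encroaches on the lumen against a fixed outer
boundary (`R1 = sqrt(R1_baseline^2 - growth/pi)`, floored at 0.05 mm), which
raises tau back toward tau0 — the homeostatic feedback that lets the graft
either find a new set point or occlude.

**Coupling.** The growth gains are weighted, scaled network output:

    alpha1(t) = [ sum_i beta1_i w1_i G_i^MIT(t) - sum_i beta2_i w2_i G_i^APOP(t) ] / 5
    alpha2(t) = [ sum_i beta3_i w3_i G_i^ECM(t) ] / 5

with signed per-cluster weights w (each in [-1,1], absolute values summing
to 1 per network) and non-negative unit-conversion scaling factors beta
(Pa^-1 day^-1 per [mRNA]).

**Therapy model.** A therapy fixes one or two clusters at `delta` times their
initial expression for the whole follow-up (delta in [0,3]; <1 inhibition,
1 baseline freeze, >1 over-expression), simultaneously in all three networks
(one gene set, three biologic mappings). It is scored by
`gain% = 100 (A_pre - A_post)/A_pre` on the 28-day intimal area, and is
viable only if the weighted mitosis and apoptosis combinations stay
non-negative throughout (cell birth/death rates cannot be negative).

## Calibration

Three GA stages, each minimizing a sum of squared deviations at the six
post-implant harvest times (2 h, 1, 3, 7, 14, 28 d):

1. **CN stage** (33 unknowns per network): fit the cluster trajectories,
   with the initial state taken from the 2-hour sample. Every
   generation-best candidate must survive all five single-cluster knockdowns
   (cluster clamped to zero; misfit of the free clusters <= Tol = 10 and no
   divergence), otherwise it is discarded and the next best promoted.
2. **Weight stage** (5 unknowns per biologic event): represent each measured
   event-rate course as a constrained linear combination of the calibrated
   networks' trajectories. Constraints are enforced by projection (clip to
   [-1,1], rescale to unit absolute sum).
3. **Scaling stage** (15 unknowns): run the coupled model per candidate
   against the intimal-thickness course; quality is reported as the
   normalized RMS percentage, PRMS = 100 ||ref - mod|| / ||ref||.

The GA is real-coded and generational: tournament selection (k = 3),
blend (BLX-0.3) crossover at rate 0.9, per-gene Gaussian mutation (rate
0.15, sigma 0.08 x range), elitism 2, population = 100 x unknowns by
default. After each run the bounds shrink to a fraction of the original
range around the incumbent best and the search restarts (2 restarts by
default), and the whole procedure repeats over independent seeded runs
keeping the argmin (default 3). All stages are deterministic under a fixed
seed.

### Parameter bounds and transformations

- Couplings A[j,k] in [-2, 2] day^-1; asymptotes B within one data range
  beyond each cluster's observed min/max.
- Modulation coefficients are bounded per power so each polynomial term
  stays O(2) over the window (|C1| <= 1e-4, |C2| <= 2.5e-3, |C3| <= 7e-2):
  wider cubic coefficients make lambda(28 d) of order 1e4 and essentially
  every random candidate diverges.
- Scaling factors are non-negative (signs of influence belong to the
  weights) with upper bound 10, and the GA searches log10(beta) on
  [-4, 1]: wall growth is exponential in beta, so on a linear scale almost
  the entire box is a fully-occluded plateau with no usable gradient.

### Identifiability devices

Two deliberate regularizations address the fact that the study design
(6 samples per curve) under-determines the coupling stages:

- **Scaling ridge** (2e-5 x ||beta||^2): without it the 15-unknown /
  6-sample scaling stage returns large mutually-cancelling coefficients
  that reproduce the untreated course but collapse under any perturbation —
  a textbook over-fitting failure. The ridge is negligible at physical
  scales (beta ~ 0.1) and strongly deters the cancelling corners.
- **Weight concentration tie-break** (WEIGHT_RIDGE = 0.01, scaled by the
  squared event-rate range): fits differing by near-null-space directions
  of the six-sample curve matrix are statistically indistinguishable but
  attribute influence, with arbitrary sign, to the wrong clusters. Among
  near-equal fits the tie-break prefers the most concentrated attribution
  (largest ||w||_2 under the unit-absolute-sum constraint). On
  well-conditioned (linearly independent) curves it perturbs the recovered
  weights by less than 1e-3.

Even with these devices, per-cluster attribution after the full chain is
only weakly identified — the dominant cluster's sampled curve is >99%
representable by the other four plus a constant. Aggregate predictions
(thickness course, 28-day area, the best achievable gains) are recovered
well; *which* cluster carries a small weight, and with which sign, is not.
This is a property of the study design, not of the optimizer, and it is why
the therapy screen is validated at ranking / order-of-magnitude resolution.

## Therapy screening

Optimization over delta is an exhaustive deterministic grid search (step
0.01 for singles; 0.05 coarse + 0.01 local refinement for pairs; ties
resolve to the smaller delta). Because a frozen cluster enters the remaining
linear dynamics as a constant input, every trajectory is affine in the
treated deltas; three base simulations per network therefore evaluate an
entire grid, with the wall ODE batched (vectorized RK4) across grid points.
Optima are re-evaluated through the adaptive-integrator route, and the two
routes are compared in the tests. The sensitivity analysis probes 11 points
spanning +/-50% of each optimal delta (clipped to [0,3]) and summarizes
robustness as the fraction of the probed grid retaining at least half the
peak gain.

## Synthetic data generator

The generator stands in for the rabbit vein-graft study tables: per-network
cluster expression, cellular-event rates and graft morphology at
{0, 2 h, 1, 3, 7, 14, 28 d}. Cluster-network parameters are
rejection-sampled until the trajectories show the canonical morphology: an
early excursion with exactly one rise/fall inversion for at least three
clusters, settling to an asymptote by day 28 (late slope < 10% of peak
slope), positive expression, non-negative event-rate combinations, and
stability under every single-cluster knockdown. Dynamically, each network
mixes a fast damped oscillation pair, a slow pair and an intermediate pure
decay through a perturbed permutation basis; cluster C (the dominant driver)
is only weakly regulated by the others, so it drives the network while its
own course is nearly cell-autonomous.

Defaults were chosen once so the untreated ligated graft reproduces the
magnitude of the studied hyperplastic response and its intervention
landscape, and then frozen: intimal area grows tens-of-fold (seed 0: 0.02 ->
1.73 mm^2, ~86x, final thickness 0.32 mm, shear recovering from 0.64 toward
6.4 Pa); inhibiting the dominant mitosis/ECM cluster (C) nearly abolishes
growth (~98% area reduction); 3-fold over-expression of the
apoptosis-dominant cluster (D) yields a moderate ~33% reduction (mostly via
network coupling — the apoptosis scaling is deliberately small so the
untreated course is mitosis-driven); the best coupled therapy performs
comparably to the best single one (~99%). Expression noise is multiplicative
(microarray-like, default 2% s.d.), event-rate and thickness noise additive
at 2% of each table's range.

What the generator does *not* emulate: per-gene variation within clusters
(only cluster means exist), inter-animal variability and paired
high/low-flow grafts (a single flow_factor scenario per dataset), missing
data, and any non-linear gene regulation beyond the cubic time modulation.
Passing the recovery tests therefore demonstrates that the pipeline is
self-consistent on study-shaped data, not that the biological inferences
transfer to real grafts.

## Numerical choices

- Network ODEs: LSODA, rtol 1e-8, atol 1e-10; divergence flagged (never
  raised) when any |G| exceeds 50x the reference scale, via a terminal
  event.
- Wall ODE: classical RK4 on a 1-hour step grid (1/24 day). The A_ECM floor
  makes the vector field discontinuous, which defeats adaptive stiff
  steppers (step-size chattering); the fixed-step path clips at the floor
  and agrees with adaptive reference integration to ~1e-8 relative in the
  smooth regime.
- The calibration surrogate for CN candidates is the exact
  eigendecomposition solution, batched over the population with
  `numpy.linalg.eig`; numerically defective candidates come back non-finite
  and are penalized. All reported objectives and the knockdown screen use
  the ODE path.
- Knockdown screening inside the GA runs at rtol 1e-6 (a Tol = 10 gate does
  not need 1e-8), capped at 10 fresh screenings per generation; final
  reported stability always uses the default tolerance.
- Grid-search determinism: no RNG anywhere in the therapy stage; ties take
  the smaller delta.

## Problem sizes

Calibration budgets in the shipped analyses, tests and acceptance run are
scaled down relative to open-ended exploration: CN stage population 30x33
for 40 generations with 2 shrinking restarts and 2 independent runs per
network; weight stage 60x5 for 60 generations; scaling stage 40x15 for 80
generations with 4 restarts. At these sizes the full chain takes a few
minutes on one core and reproducibly reaches thickness PRMS < 1%. Therapy
screens use the full delta grids (301 points per single, 61x61 coarse + 11x11
refinement per pair).

## Known limitations

- Per-cluster attribution (weights, scaling) is under-determined by the
  six-sample design; see above. Consequences: downstream per-cluster therapy
  predictions from a chain-calibrated model inherit attribution noise, and
  the over-expression arm of the screen is the least reproducible quantity.
- The wall model tracks areas only (no spatial wall structure, no medial /
  EEL dynamics, no pulsatility); external radius and pressures are not part
  of the extracted subset.
- Therapies are constant-from-implantation only; late-onset or time-varying
  dosing is out of scope.
- The geometry closure (fixed outer boundary, lumen encroachment) is the
  simplest one consistent with the shear law; thickness is reported as
  R1_baseline - R1(t).
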