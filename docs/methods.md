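# Methods

## Problem setting

A cell-culture seed train expands a CHO suspension culture through
bioreactors of increasing working volume (here 40 L → 320 L → 2 160 L)
before inoculating the production vessel. Offline samples are taken
roughly once a day, so each 72–96 h scale contributes only 4–5 data
points (including inoculation), the measurements carry ~5%
multiplicative error, and growth behaviour varies between runs and
between cultivation systems. Model-based prediction of the remaining
process future — primarily of viable cell density, the quantity that
drives transfer decisions — therefore requires re-estimating model
parameters whenever a new sample arrives, from very little and noisy
data. This package implements that iterative updating loop and the
benchmarking machinery around it.

## Kinetic model

The batch model tracks total and viable cell density `Xt`, `Xv`
(1e9 cells/L, numerically equal to the conventional 1e6 cells/mL) and
the concentrations of glucose, glutamine, lactate and ammonium (mM).
The algebraic rate laws are Monod-type:

    mu    = mu_max * cGlc/(cGlc + K_Glc) * cGln/(cGln + K_Gln)
    mu_d  = mu_d_min + mu_d_max * K_d_Glc/(cGlc + K_d_Glc)
    qGlc  = q_Glc_max * cGlc/(cGlc + k_Glc)
    qGln  = q_Gln_max * cGln/(cGln + k_Gln)
    qLac  = Y_LacGlc * qGlc
    qAmm  = Y_AmmGln * qGln

and the mass balances

    dXv/dt   = (mu - mu_d) Xv
    dXt/dt   = mu Xv - k_lys (Xt - Xv)
    dcGlc/dt = -qGlc Xv
    dcGln/dt = -qGln Xv - k_Gln_decomp cGln
    dcLac/dt =  qLac Xv
    dcAmm/dt =  qAmm Xv + k_Gln_decomp cGln

Viability `Via = 100 Xv/Xt` is a derived observable, not a state. The
model is a standard member of the double-Monod CHO batch family:
growth limited by glucose and glutamine, death accelerating on glucose
exhaustion, uptake saturating in its substrate, constant product
yields, first-order lysis of dead cells and abiotic glutamine
decomposition feeding ammonium. It has 14 explicit parameters; richer
variants of this model class add death-phase/apoptosis terms that are
irrelevant for exponential-phase seed trains and are deliberately
omitted. The rate laws sit behind a small surface (`specific_rates`,
`ode_rhs`) so an alternative law set can be swapped in.

Integration uses `scipy.integrate.solve_ivp` with LSODA,
rtol 1e-8 / atol 1e-10. The dynamics are smooth, but near-depleted
substrates can undershoot zero by the solver tolerance; post-step
states are clipped at 0 (logged). An independent fixed-step classical
RK4 oracle at dt = 0.01 h agrees with the adaptive solution to better
than 1e-6 relative on the default parameterization; the test suite
freezes that oracle value as a regression anchor.

## Seed-train chaining and passaging

Passaging is modelled as ideal instantaneous dilution with fresh
medium: a broth fraction `f` is transferred, cell densities scale by
`f` (viability ratio preserved) and each concentration becomes the
convex combination `f*c_end + (1-f)*c_medium`. Two rules set `f`:
dilution to a target inoculation density (default, 0.4e9 cells/L) or a
fixed split ratio. A target above the available density is an explicit
infeasibility error — dilution cannot concentrate cells.

For *prediction* the default anchor policy treats each scale's initial
state as known (`measured_anchors`): simulation restarts from the
measured state at the current sampling point and is re-anchored to the
measured inoculation state at each later scale boundary. This isolates
the effect of the estimated parameters from propagated inoculation
errors, which is the study assumption this package reproduces;
`simulated_passaging` chains the mixing arithmetic instead and is
available for end-to-end simulation studies.

## Estimation objectives

At sampling point `t_i` the estimation horizon holds the `n` most
recent points per the selected mode — growing (left bound fixed at
`t_1`), moving of fixed length `n`, or per-scale growing (left bound
resets at each scale start). The free parameters (default: `mu_max`,
`k_Glc`, `k_Gln`, `K_Glc`, `K_Gln`, `Y_LacGlc`, `Y_AmmGln`; the
remaining seven are unidentifiable without stationary/death-phase data
and stay fixed) are bounded at prior ±50%.

WLSE minimizes `J(p) = Σ_j Σ_i w_m,ij (y_m,ij - y_ij(p))²` with
`w_m,ij = 1/y_j,max` over the horizon (division by the maximum
experimental value; the weights deliberately carry the printed 1/y
dimension rather than 1/y²). MHE adds a forgetting term and a
parameter-change penalty:

    J(p) = WLSE(p) + Σ_ij w_p (y_ij(p) - ŷ_ij)² + Δp c_Δp
    Δp   = (γ/n_p) ||p̂ˢ - pˢ||₂          (parameters scaled to [0,1])

where `ŷ` are model values simulated with the prior vector `p̂`. The
defaults `w_p = 4/n` and `c_Δp = 1/n` make prior knowledge dominate
when only 2–3 points are available and fade as the horizon grows. The
forgetting term is implemented against the *model* values
`(y(p) - ŷ)²`; the variant written against measured values
`(y_m - ŷ)²` is constant in `p`, cannot steer the optimizer, and is
kept behind `forgetting_form="measured"` purely for reproducing
objective values. γ defaults to 1 and is exposed in the config.
`w_p` applies uniformly across variables; missing cells drop out of
all sums while `n` keeps counting sampling times.

## Optimizer

Minimization runs in the [0,1]-scaled bound box: multistart
Nelder–Mead (up to 3 deterministic starts — the prior, and the
lower-/upper-quartile points of the box; 2 000 evaluations default
budget) followed by a bounded trust-region least-squares polish
(`scipy.optimize.least_squares`, TRF, finite-difference Jacobian with
`diff_step` 1e-4). The polish exists because the simplex collapses far
from the optimum along weakly identifiable directions — Monod
constants an order of magnitude below the prevailing substrate level
move the objective only slightly — while a Gauss–Newton-type step
follows such flat valleys readily; on noiseless data it recovers all
seven free parameters to <0.01%. For MHE the penalty `Δp c_Δp` enters
the polish as a smoothed residual (`ε = 1e-18` inside the norm to keep
the gradient finite at `p = p̂`); every candidate is accepted on the
exact objective, and the returned objective value never exceeds the
value at the start point. Everything is deterministic: there is no
stochastic component in either stage.

The workflow layer runs its per-step estimations with a single start
(the just-updated prior) — each step is warm-started and, under MHE,
regularized toward that prior, so the extra starts buy nothing at
triple the cost. Direct calls to `estimate` keep the 3-start default.

## Iterative learning workflow

Within a seed train (sample-to-sample cycle), each new sampling point
triggers horizon selection, re-estimation (under per-scale parameter
sets only the current scale's vector moves; untouched scales keep
theirs bit-identically), prediction of all remaining sampling points,
and assessment against the measurements that were not used. Steps
whose horizon holds fewer than two points (the inoculation sample of a
new scale under per-scale horizons) carry the prior forward unchanged
but still predict. An estimation failure is logged and the prior
carried forward rather than aborting the cycle.

Between seed trains (batch-to-batch cycle), train `m` takes its prior
from the chained estimate over the most recent `B` trains, processed
sequentially from the nominal prior (`B = 0`: all runs independent
from nominal). `B` is the arrival-cost window: chaining parameter
knowledge rather than pooling historical data keeps the estimation
cost per step flat. Chain segments are memoized, and a train's own
pass doubles as the chain segment that starts where its prior started.

## Evaluation metrics

Relative prediction error: `100 |predicted - measured| / measured`,
computed per future sampling point and variable. A step's error is the
mean over its prediction-horizon points (the intra-step aggregation is
not prescribed anywhere; the mean is the obvious choice and is
documented as such); per seed train the mean/min/max over updating
steps is reported, aggregated over the ensemble for benchmarking.
Reports focus on viable cell density, the variable of interest; all
six variables are assessed. When strategies with different fixed
horizon lengths are compared, all are summarized from the same first
prediction horizon (the largest `evaluation_start`), so no strategy is
scored on horizons another cannot predict. The precision-weighted
prediction error divides the relative error by the intermediate
precision of the assay (4.7% CV default); values near 1 mean the model
is at the irreducible measurement-uncertainty floor. Percentages and
ratios are reported to one decimal.

## Synthetic data generator

Industrial seed-train data are proprietary, so the generator emulates
their statistical structure: 3 scales (40/320/2 160 L) over 96/72/72 h
with 24 h sampling (5+4+4 points incl. inoculation), independent
multiplicative Gaussian measurement noise with 5% CV on every observed
cell (negative draws resampled; applied uniformly to all six
variables, configurable per variable), a per-train `mu_max` factor
with 5% CV (batch-to-batch variability), and a 0.93 factor on the
first stirred scale's `mu_max` (adaptation from the shaken to the
stirred system). The default ensemble size is 10 seed trains. Nominal
kinetics and the inoculation state (0.4e9 cells/mL, 30 mM glucose,
4 mM glutamine, metabolites ≈ 0) are package defaults chosen once for
realistic 3–4-day exponential CHO profiles with appreciable substrate
depletion (glucose 30 → ~9 mM, glutamine 4 → ~0.7 mM over 96 h); the
emulated industrial process publishes no numbers.

What the generator does *not* emulate: lag phases, stationary/death
phases, assay drift or autocorrelated errors, missing samples, and
any upstream shake-flask scales. Passing tests therefore show that the
estimation machinery behaves correctly under the stated noise and
variability structure — not that the default kinetics describe any
particular real cell line.

## Problem sizes and numerical choices

The benchmark experiments use the study-scale setup throughout: 10
synthetic seed trains, 13 sampling points each, 11 assessed updating
steps per train. One full MHE per-scale pass over the 10-train
ensemble with a 1-train arrival-cost window takes on the order of two
minutes on a single core; the dominant cost is ODE integrations inside
the estimation loops (a few hundred per updating step). Ties and
degenerate inputs are handled explicitly: degenerate bounds are
rejected at scaling, horizons shorter than two points skip estimation,
empty prediction horizons yield empty assessments, and columns without
a positive value cannot be weighted and raise.

## Known limitations

* The kinetic model is fixed to the exponential-phase batch family;
  fed-batch feeding terms, temperature/pH effects and product titer
  are out of scope.
* Identifiability of the Monod constants depends on the data actually
  exercising the saturation terms; with barely-depleted substrates the
  penalty/forgetting terms (not the data) decide those components.
* The arrival-cost chaining passes point estimates only; no parameter
  covariance or Bayesian posterior is propagated.
* Relative prediction error is undefined at non-positive measurements,
  so variables near zero (early metabolites) can dominate their own
  error summaries; ranking therefore uses viable cell density.
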