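# Methods

This note documents the model, the numerical choices, and the synthetic
study conditions implemented in `spindlescale`, together with their known
limitations. Units are micrometres (um), seconds (s) and piconewtons (pN)
throughout; drag coefficients are pN s/um.

## The stoichiometric pulling model

The cell is a sphere of radius `R`, taken as the cube root of the average
cell volume of the developmental stage. Two centrosomal asters nucleate
microtubules isotropically at rate `n_dot = N_T * lambda` so that the
steady-state microtubule number per aster is `N_T`; microtubules grow at
`V_g` and undergo catastrophe at rate `lambda`, giving mean length
`V_g / lambda`. Motors anchored on the cortex bind at most one
microtubule each. The fraction of motors at cortical position `Y` engaged
with aster `i` is a deterministic coarse-grained field `P_i(Y, t)`:

    dP_i/dt = Omega_i (1 - P_1 - P_2) - kappa P_i,

with `kappa` the unbinding rate. The `(1 - P_1 - P_2)` factor is the
stoichiometric competition between the asters for free motors. The
impingement rate adopted here is the closed form

    Omega_i = N_T lambda (r^2 / 4 d_i^2) exp(-lambda d_i / V_g),

where `d_i` is the pole-to-cortex distance and `r` the motor capture
radius: nucleation flux times the geometric capture fraction of an
isotropic emitter times the probability that a microtubule survives to
length `d_i`. `impingement_rate` is the single place to substitute an
alternative prefactor.

Each bound motor pulls the pole toward its anchor with force `f0`; the
total pull is the surface integral `F_i = (M f0 / A) * Int P_i xi_hat dA`
with `M = round(rho A)` motors on area `A = 4 pi R^2`. Pole motion
balances this pull against cytoplasmic drag `eta` and a viscous coupling
`nu` to the chromosome plates acting along the spindle axis `s_hat`:

    eta dx_i/dt + nu ((dx_i/dt - dc_i/dt) . s_hat) s_hat = F_i.

Chromatid separation is not modelled mechanistically; it is imposed as
`Delta_c(t) = c_f (1 - exp(-t / tau_c))` with `c_f = 6.2` um and
`tau_c = 29` s, reflecting its observed near-invariance with cell size.
The plates ride the instantaneous pole midpoint, separated by `Delta_c`
along `s_hat`; their axial velocity is the analytic derivative of
`Delta_c`. Pinning the plates to the pole midpoint (rather than to the
cell centre, or letting the midpoint evolve freely) was a genuinely open
choice; it keeps the spindle internally consistent and makes the
chromosome trace exactly the imposed law. With `nu = 0` and frozen
chromosomes the equations reduce to the plain aster-positioning balance
`eta dx_i/dt = F_i`.

### Default parameters

| parameter | symbol | default | units |
|---|---|---|---|
| microtubules per aster | N_T | 5000 | – |
| growth velocity | V_g | 1.0 | um/s |
| catastrophe rate | lambda | per stage (0.038–0.945) | 1/s |
| motor density | rho | 0.12 | 1/um^2 |
| motor capture radius | r | 1.5 | um |
| unbinding rate | kappa | 0.05 | 1/s |
| motor force | f0 | 5 | pN |
| pole drag | eta | 450 | pN s/um |
| pole–chromosome coupling | nu | 50 | pN s/um |
| chromosome plateau | c_f | 6.2 | um |
| chromosome time constant | tau_c | 29 | s |

Per-stage geometry (stage, cell radius, initial pole separation): 2: 23,
13; 4: 18, 11.2; 8: 14, 9; 16: 11, 7.5; 32: 9, 6.4; 64: 7.3, 5.4 (um).

## Numerics

**Surface quadrature.** The cortex is discretised with a Fibonacci
generative-spiral lattice of equal-area patches (default n = 2000,
minimum 128). The lower hemisphere is the exact antipodal image of the
upper, so mirror-symmetric pole configurations see exactly
mirror-symmetric quadrature; a raw spiral's O(1/n) asymmetry otherwise
acts as a spurious force that slowly drifts the pole pair off centre.
Final lengths change by <1% under mesh doubling at default settings.

**Time stepping.** Field and poles advance with an explicit first-order
update, guarded by the stability requirement
`dt * (Omega_1 + Omega_2 + kappa) < 1` at every patch (the sum form is
what guarantees `P_1 + P_2 <= 1`); violations raise an error naming the
offending `dt`. The default is `dt = 0.01 s`: at the 32- and 64-cell
configurations the equilibrium pole sits close enough to the cortex that
the local impingement rate reaches ~24 and ~68 1/s, so coarser steps are
rejected by the guard. Final lengths at `dt` 0.01/0.005/0.0025 agree to
four decimals. Trajectories are sampled every 10.3 s (the acquisition
interval) to `t_end = 300 s`.

**Fused kernel.** The production path is a numba-compiled loop
implementing exactly the per-step math of the public operations; a pure
per-operation reference path exists alongside it and the test suite
asserts agreement to machine precision. Dynamic steady states were
additionally cross-checked against an independent quasi-static oracle
(closed-form steady-state field, root of the axial force balance): the
two agree to <0.1%.

**A non-obvious model property.** At *fixed* cell radius the equilibrium
spindle length is monotonically *increasing* in `lambda` (at the 8-cell
geometry: D* = 4.7, 10.3, 15.0, 19.0, 27.0 um for lambda = 0.005, 0.04,
0.164, 0.33, 1.3). Because nucleation is tied to the catastrophe rate,
small `lambda` produces a weak, distance-undiscriminating (and hence
centering) engagement field, while large `lambda` concentrates engagement
on the near cortex and pulls the poles outward. The familiar
"higher catastrophe rate, shorter spindle" trend across development
emerges only because the cell radius falls jointly as the rate rises.
Relatedly, a *uniformly* engaged cortex is centering, not polarising: the
force integrand is a unit vector weighted by area, and the far hemisphere
always holds the larger area (mean unit-vector component -0.334 for a
pole at R/2, verified by Monte-Carlo integration). The outward pull that
elongates the spindle comes entirely from near-cortex saturation making
the effective field non-uniform.

## Catastrophe-rate inference

`lambda` is the sole free parameter per stage; all others are fixed. The
objective is the squared mismatch of pole-to-pole distance summed over the
target's time points, with the simulation linearly interpolated onto the
target grid. Differential evolution (scipy, rand/1/bin, mutation 0.7,
crossover 0.9, 50 candidates per generation, bounds [0.001, 10], no
polishing) minimises it; the search stops when the population's lambda
spread falls below 1e-3 or at the generation cap (default 25). Candidates
whose simulation fails (stability guard or pole escape at extreme lambda)
receive a large finite penalty so the search simply avoids them. Inside
the search loop simulations run on a coarse 512-patch mesh at dt = 0.01 s;
the reported error is re-evaluated on the full 2000-patch mesh at the
optimum. Runs are deterministic given the seed; batch fits derive
order-independent per-stage seeds from the base seed.

Problem sizes in the shipped tests and acceptance script are scaled to a
single CPU: recovery tests use 128–512-patch meshes, populations of
8–20 and 2–16 generations; the acceptance run uses the full 50-candidate
population with 10 generations. At these settings the 64-cell rate is
recovered to ~0.1% and all six stage rates to within 10% (the 2-cell
rate, 0.038, is the hardest: it sits three orders of magnitude from the
upper search bound on a linear axis).

## Trajectory quantification

Pole traces are fitted with `f(t) = L1 + L2 / (1 + exp(-(t - t0)/tau))`;
final length `FLPP = L1 + L2` and elongation rate
`ERPP = (L2 / 4 tau) * 60` um/min (the explicit x60 is pinned by the
consistency of the published example triplet: initial 5.56 um, final
11.17 um, rate 2.97 um/min). Chromosome traces are fitted with
`f(t) = a (1 - exp(-t/k))`; `FLCC = a`, `SRCC = (a/k) * 60` um/min
(pinned by a = 5.93 um, rate 15.52 um/min, hence k = 22.92 s).
Initialisation follows the data (L1 = first sample, L2 = range, t0 =
half-range crossing, tau from the steepest finite-difference slope), with
multi-start over +/-50% perturbations on non-convergence. Parameters are
constrained to a data-supported box (t0 within one span of the record,
amplitudes within a few data ranges, tau <= 10 spans): without it the
sigmoid can escape to a degenerate quasi-linear branch (t0 -> -inf, L1 ->
-inf with L2 compensating) that leaves FLPP finite but makes ERPP
meaningless. Noiseless round trips recover parameters to 1e-6 relative.

Scaling is quantified as the ordinary-least-squares slope of
log(quantity) on log(cell size) — the power-law exponent; a linear-axes
option exists and the convention travels with the result. Cell size is
the cube root of cell volume. The elongation-rate transition is a
continuous flat-then-linear fit with the breakpoint profiled over a grid
that includes the observed sizes. One-way ANOVA F = MS_between/MS_within
is computed directly from the decomposition (infinite F flags zero
within-group variance) and is cross-checked against scipy in the tests.
Stage averages interpolate each cell onto the overlapping time range at
10.3 s spacing and report pointwise mean and sample SD.

## Kymograph readout

Frames are rows of a time-by-position intensity matrix. Pole detection
takes the two most prominent peaks above 3x the scaled-MAD noise floor
(ties broken toward the profile centre); centres are refined by fitting
`a exp(-((x-b)/c)^2) + d` in an 11-sample window. The Gaussian is
implemented exactly as printed in the source analysis — without the
conventional factor 2 in the exponent — so `c` is sqrt(2) times the usual
sigma. Chromosome peaks are searched strictly between the refined pole
centres; frames with failed or out-of-bounds detections carry NaN and are
excluded from all downstream fits, never fabricated. Distances convert
through the pixel size; 3D spot distances use the anisotropic voxel
(0.1, 0.1, 0.5) um. Anaphase onset is the last frame before the
chromosome separation exceeds its pre-rise baseline (median + 3
scaled-MAD) for two consecutive frames.

## Ablation analysis

Velocities are OLS slopes inside the windows (-8, 0) s and (4, 12) s
around the cut (both endpoints open; the 0–4 s severing/recoil transient
is excluded by construction). The response reports before/after
velocities of pole and chromosome separation, their differences, and the
percent change of the pole elongation rate.

## Microtubule classification

A trace is *interpolar* if either end lies within `pole_radius` (default
0.5 um, exposed as a flag — no published threshold exists) of a
centriole; *mid-spindle* if both ends fall strictly inside the open slab
bounded by the two chromosome-plate planes and neither end is
pole-proximal; *other* otherwise. Interpolar takes precedence when both
predicates hold, so a microtubule running from a pole past the near plate
toward the far plate is interpolar. The slab (rather than a convex hull)
is the assumed reading of "between the chromosomes". Classification is
invariant under rigid motions of the whole configuration.

## Synthetic study conditions

Every generator is a pure function of (configuration, seed).

**Atlas.** The embryo is an ellipsoid (length 51 um wild-type — 62 um
large, 37 um small variants — width 30 um); cell volumes halve exactly at
each division, which reproduces the measured 2-cell size scale (~23 um)
and ignores lineage-level volume asymmetry. Per cell: final spindle
length follows `FLPP ∝ size^0.75` anchored at 11.17 um for an 11-um
cell; the elongation rate is flat (2.97 um/min scale) above the 12-um
transition size and declines proportionally below it; chromosome
separation follows `FLCC ∝ size^0.09` anchored at 5.93 um, which lands
the 2-cell plateau at ~6.2 um; the chromosome time constant stays at
29 s. Cell-to-cell scatter is lognormal (4%), measurement noise additive
Gaussian (0.2 um), sampling every 10.3 s. What passing round-trip tests
show is that the analysis recovers exponents and breakpoints from data
with this noise structure — not that real embryos obey the generator's
clean power laws, stage-synchronous onsets, or symmetric volume halving.

**Kymographs.** Gaussian peaks of the fitted shape at +/- D/2 around the
field-of-view centre; noise is Gaussian with variance proportional to the
local mean (Poisson-like), parametrised by the peak SNR.

**Ablation.** Pole separation elongates at 0.04 um/s before the cut and
at 1.4x that during the first 15 s after it, then relaxes; chromosome
separation proceeds at a constant 0.12 um/s throughout. A constant rate
(rather than the global exponential law) is used deliberately: over the
~30 s record the law's curvature alone would change the inter-window
chromosome slope by ~33%, contradicting the observed invariance the
cohort is meant to emulate. Controls share the pre-cut slopes with no
jump.

**Microtubule sets.** End points are placed to realise each class's
predicate with margin, so requested per-class counts are recovered
exactly by construction.

## Known limitations

- The impingement prefactor is a first-principles stand-in for the
  original implementation's (unpublished) form; equilibrium lengths are
  sensitive to it. With the adopted form and the tabulated per-stage
  rates, the six equilibria give a 2-to-64-cell fold change of ~2.08 and
  a log-log exponent of ~0.65 — between the two published headline values
  (~2-fold and 0.75), which are themselves mutually inconsistent over
  this radius range (a 2.0-fold change corresponds to an exponent of
  0.60, and an exponent of 0.75 to a 2.36-fold change).
- The coarse-grained motor field is deterministic; motor-number noise,
  overlapping/stacking motor regimes, non-spherical cells, and explicit
  kinetochore or central-spindle mechanics are out of scope.
- Chromosome dynamics are imposed, so simulated chromosome traces carry
  no information beyond the law and serve only as consistency checks.
- No cortical repulsion acts near the boundary; at extreme parameter
  values the poles approach the cortex until the stability guard or the
  escape check stops the run.
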