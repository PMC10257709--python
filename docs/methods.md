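# Methods

## Model

`oscidisk` simulates N two-dimensional disks in a rectangular box (width 20,
height 150 in units of the rest radius) with a bottom wall interrupted by an
orifice of width D = 2.8, centered on the box. Each particle i obeys

    m dv_i/dt = F_drive + F_contact

with two active ingredients:

1. **Driving.** A Helbing–Farkas–Vicsek-style self-propulsion force
   `F_drive = m (v_f e_d - v_i) / tau` relaxes the velocity toward the free
   speed `v_f` along the fixed goal direction `e_d = (0, -1)`. An isolated
   particle starting at rest follows `|v|(t) = v_f (1 - e^(-t/tau))`
   exactly; this closed form is the integrator's primary oracle.

2. **Active deformation.** Each radius is prescribed kinematically,
   `r_i(t) = r0 (1 + A sin(omega t + phi_i))`, with one random phase
   `phi_i ~ U[0, 2 pi)` per particle. `A = 0` gives a monodisperse rigid
   system; `omega = 0` freezes distinct radii (a polydisperse rigid system).
   The radii carry no inertia: deformation enters the dynamics only through
   the overlaps.

Contacts are linear springs with velocity-proportional tangential friction.
For particles i, j with overlap `xi_ij = (r_i + r_j) - d_ij > 0`:

    F_ij = xi_ij * [ k_n e_n + k_t ((v_j - v_i) . e_t) e_t ]

where `e_n = (x_i - x_j)/d_ij` points from j to i (so the normal term is
repulsive) and `e_t = rot90(e_n)`. Wall contacts use the same law with the
particle's own velocity in the tangential term. Both force terms scale with
the overlap, so friction weakens as particles stiffen — which is why the
sweep over `k_n` keeps `k_t = 2 k_n`.

All quantities are dimensionless with `m = r0 = tau = 1`. Reference values:
`N = 200, k_n = 500, k_t = 1000, v_f = 3.3, D = 2.8, dt = 1e-4,
dt_k = 0.5` (recording interval), `T = 5000`.

## Geometry and bookkeeping

* The bottom wall consists of two segments flanking the orifice; the side
  walls run the full box height. Wall contact uses the distance from the
  particle center to the closest point of each segment; an orifice lip is
  simply the endpoint case (`xi = r - |center - lip|`, normal along
  `center - lip`), the standard DEM treatment of a convex corner.
  Simultaneous contacts with several boundary elements are summed.
* An **exit event** is recorded when a particle center crosses `y = 0`
  moving downward; upward re-entry followed by another crossing counts
  again and is tallied separately (it essentially never happens in
  practice).
* Particles reaching `y = -15` are **recycled**: rejection-sampled into
  `(2, 18) x (100, 150)` with no overlap against current particles, velocity
  reset to zero (configurable to keep-velocity; zero avoids injecting
  kinetic energy at the top). If placement fails after 10^4 attempts the
  particle is parked below the removal line and retried next step, so N is
  always conserved.
* **Initialization** places particles sequentially at uniform random
  positions at least one radius from every boundary, redrawing any candidate
  that overlaps an existing particle, so the initial state is contact-free.

## Integration

The equations are integrated with velocity Verlet at `dt = 1e-4`. Forces
depend on velocity (driving and friction), so the new acceleration is
evaluated at the predicted velocity `v + a dt` and the velocity is then
corrected with the mean of old and new accelerations — one force evaluation
per step. At the reference parameters the stiffest timescale is the contact
period `2 pi sqrt(m/k_n) ≈ 0.28`, resolved by ~2800 steps; the fastest
radius oscillation (`omega = 100`) is resolved by ~630 steps. The compiled
(numba) kernel and a pure-numpy reference step implement the identical
scheme and are asserted to agree to ~1e-9 over thousands of steps.

Neighbor search uses a Verlet (distance-cutoff) list with cutoff
`2 r0 (1 + A) + skin` (skin 0.4), rebuilt by an all-pairs scan whenever any
particle has moved more than skin/2 since the last build (a recycled
particle always triggers a rebuild). This is purely an efficiency device:
results are identical to the all-pairs force oracle, which the tests check.

Determinism: the per-run seed drives initial placement and phases (numpy
`default_rng`) and in-kernel reinjection draws (numba's seeded RNG);
identical (config, seed) inputs give byte-identical event logs.

## Flow statistics

* **Flow rate** Q is the least-squares slope of the cumulative exit count
  versus time. The default window starts at `t = 100` or the first exit,
  whichever is later (the transient is over well before `t = 100` in all
  systems studied; the window is configurable). When the caller supplies
  the run length T, the final count is anchored at T so an arrested tail
  pulls the slope down. The identity estimator `Q = 1/<dt_out>` is reported
  alongside; the two agree for steady flows. A run whose last exit precedes
  `0.9 T` is flagged **arrested**.
* **Power-law fit.** Inter-exit intervals are fitted with the
  Clauset–Shalizi–Newman procedure for continuous data: for each candidate
  cutoff (every unique sample value leaving at least `min_tail = 10` tail
  samples) the exponent is the closed-form MLE
  `alpha = 1 + n / sum(ln(x_i/x_min))` and the candidate minimizing the
  Kolmogorov–Smirnov distance between tail ECDF and fitted CDF wins, ties
  toward the smaller cutoff. The KS-optimal cutoff has substantial upward
  variance within the tail (a known property of the method); synthetic
  recovery tests therefore check the exponent against the generator truth
  and, where Phi is the target, decompose at the generator's stored cutoff.
  The goodness-of-fit bootstrap is not implemented: only `alpha` and
  `dt_out_min` feed the downstream classification.
* **Bursts, clogs, Phi.** Intervals at or above the fitted cutoff are
  clogs; maximal runs of sub-cutoff intervals merge into single bursts.
  `Phi = <dt_f> / (<dt_c> + <dt_f>)` classifies the flow (0 clogged,
  1 flowing); `alpha <= 2` forces `Phi = 0` because the mean clog time
  diverges. Note that with this mean-based definition, adding a clog
  *shorter* than the current mean clog raises Phi; the property suite
  asserts the monotonicities that actually hold (lengthening any clog never
  increases Phi, a first clog lowers it from 1).
* **Bulk observables** are evaluated in the region `x in [2,18],
  y in [2,30]` (area 448): contactless probability `<P_free>`, density
  `<rho> = <n>/448`, contacting count `<n_c>` and mean overlap `<xi_c>`
  (per contacting in-region particle, the mean overlap with its partners,
  averaged over those particles, then over frames). Membership is by
  particle center; contact partners outside the region count. Frames with
  no in-region particle are skipped for `P_free`/`xi_c` and counted.
* **Resonance utility.** The driven-damped-oscillator amplitude
  `A0 ∝ 1/sqrt((2 omega omega0 zeta)^2 + (omega^2 - omega0^2)^2)` is
  provided for comparing measured Q(omega) curves with single-peak
  oscillator response; it diverges (returns inf) at the undamped resonance.

## Experiments

Sweeps run one simulation + analysis per (grid value, replicate); per-run
seeds derive deterministically from a master seed and the grid index, and
sweeps with an output directory are resumable through a manifest. `omega*`
is the grid argmax of the seed-mean flow rate; its uncertainty combines, in
quadrature, half the local grid spacing with the bootstrap-over-seeds spread
of the argmax (a pragmatic substitute for a formal error model, flagged as
such). The scaling fit reports the one-parameter form `omega* = k_n^gamma`
(zero intercept on log-log axes, the headline), a two-parameter variant with
free prefactor, and the fixed-exponent prefactor `c` in
`omega* = c sqrt(k_n)`.

## Problem sizes for tests and the acceptance script

Full-fidelity resonance studies (N = 200, T = 5000–25000, fine omega grids)
are multi-hour batch jobs. The shipped tests and `scripts/acceptance.py`
use reduced systems chosen to preserve the constriction physics — same
D, k_n, k_t, v_f and dt, shorter box and fewer particles:

* **N = 60, box height 60, reinjection y in (40, 60), T = 400–500** for
  single-condition checks (arrest at A = 0, amplitude monotonicity, the
  omega sweep at the reference stiffness).
* **N = 100, box height 80, T = 400–500** for the omega*-vs-k_n study. At
  N = 60 the column above the orifice is too light for the stiffest system
  (k_n = 1500): overlaps become so shallow that the resonance flattens and
  the measured peak drifts low — a finite-size artifact that disappears at
  N = 100, where omega* = {15, 22, 33} for k_n = {150, 500, 1500} and the
  one-parameter fit gives gamma ≈ 0.5 with prefactor ≈ 1 on sqrt(k_n).

These sizes make the scaled flow rates smaller than full-scale ones (less
hydrostatic load above the orifice), so tests assert locations, orderings
and ratios — the resonance position, monotonicity in A, the arrest ratio —
rather than absolute Q values.

## What the synthetic generators do and do not emulate

`sample_power_law` and `sample_intermittent_log` produce i.i.d. draws with
exact ground truth (inverse-CDF power law; alternating exponential burst
gaps and power-law clogs with fixed burst length). Real discharge logs have
correlated intervals, finite-T censoring of long clogs and a soft crossover
rather than a sharp cutoff, so estimator tests on these generators validate
the statistics pipeline, not the physics of any particular run.

## Known limitations

* 2D only; radius oscillation is kinematic (no area conservation, no
  inertia of the deformation mode).
* No static friction: tangential forces are purely viscous, so, e.g., an
  arch is stabilized by normal forces and geometry alone.
* The flow-rate regression window and the omega* uncertainty recipe are
  pragmatic defaults, documented above, not uniquely determined choices.
* Scaled-down systems shift absolute flow rates; only full-scale runs
  (config defaults) are quantitatively comparable to full-fidelity results.
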