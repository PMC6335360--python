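# Methods

## The model

`omvsim` simulates horizontal, rightward saccades in a closed rate-based
control loop with four interacting parts.

**Collicular command.** A dummy superior-colliculus unit emits a step
`y_d` whose rate equals the target eccentricity (1 Hz per degree),
switched on at the command time `t_on` and silenced by the end-of-trial
cut-off. An omnipause-style gate keeps the burst pathway silent before
`t_on`: cerebellar drive alone cannot initiate a movement.

**Brainstem burst generator with internal feedback.** The medium-lead
burst neurons are one grouped unit,

    u(t) = [A * s * (1 - exp(-(y_c + y_d - k \int u dt) / sigma))]_+

with `A = 1100 Hz`, `sigma = 16`, and a displacement integrator whose
gain `k = 0.72 < 1` makes the internal displacement estimate inaccurate:
without cerebellar correction the raw integral — and with it the eye —
overshoots the target by roughly `1/k`. The motivation scale `s <= 1`
models reduced vigor by shrinking the burst amplitude. Burst rates are
rectified at zero; braking is carried by the cerebellar pathway, not by
negative bursts.

**Oculomotor plant and tonic hold.** The eye is the overdamped
second-order system `k1 θ'' + k2 θ' + k3 θ = m(t)` with
`k1, k2, k3 = 0.003 s², 0.6 s, 4` (characteristic times ≈ 5 ms and
145 ms). The motoneuron drive is the matched pulse+step

    m(t) = k2 * u(t) + k3 * \int u dt,

i.e. the burst acts as a velocity command through the viscous
coefficient while a neural integrator's tonic charge holds position
through the stiffness. With this mapping the eye tracks the integrated
burst (1 Hz ≈ 1 deg/s), `k = 0` produces an unbounded position ramp and
`k = 1` an accurate but slower saccade, which is the behaviour the
burst-generator equation is meant to produce. The plant advances by the
exact zero-order-hold discretization (matrix exponential, precomputed
once per step size); a forward-Euler variant exists as a cross-check. A
timed switch, fired a fixed 150 ms after detected movement onset, cuts
off the burst and the vermal inputs and clamps the eye at the reached
position (it stands in for omnipause/fixation machinery at the end of
the movement).

**Bilateral oculomotor vermis.** Two mossy-fiber channels carry the
task state: `MF_target`, a target-proportional rate (`lam = 2` Hz/deg)
with a Gaussian long-lead build-up (`alpha = 15 ms`) before `t_on`, and
`MF_burst`, the efference copy of `u`. Each side of the vermis holds a
granular reservoir of `N = 100` leaky rate units,

    tau * dz/dt = -z + f(W_mf m - rho * W z),    z >= 0,

with `tau = 20 ms`, logistic `f` saturating at `f_max = 1`, nonnegative
sparse recurrent weights `W` (density 0.1, drawn uniform in [0, 0.2],
normalized to unit spectral radius) acting inhibitorily, and spectral
radius parameter `rho = 0.5`. Input weights are uniform in [-30, 30].
Each Purkinje "layer" is the total population projection onto one
fastigial nucleus — a scalar readout `y_pc = w_pf_pc · z`. Fastigial
activity combines PC inhibition with direct mossy excitation,
`y_cfn = -20 * y_pc + w_mf_cfn * u`, and the net correction returned to
the burst generator is `y_c = 0.02 * y_cfn_contra - 0.02 * y_cfn_ipsi`.
Only the `w_pf_pc` vectors are plastic.

## Learning

The criterion for one trial is the time-weighted cumulative gaze error
plus a quadratic penalty,

    J = Σ_t |y_d(t) - θ(t)| Δt + γ ||w_pf_pc||²,   γ = 1e-4,

with the desired displacement equal to zero before the command and to
the target afterwards. Minimization uses no analytic gradients: a BFGS
iteration runs on forward finite-difference gradients (step
`1e-6 * (1 + |x|)`) with an Armijo backtracking line search on the
objective alone. The batched simulator makes this affordable — a full
finite-difference gradient is a single run with one column per
perturbed parameter and target, and trials stop simulating once every
column's eye is held (the remaining cost is linear in the frozen
error).

Training is organised in epochs. Six exploration epochs each draw 8
random targets uniformly in 4–20° from the seeded stream and take up to
10 quasi-Newton steps. A saturation phase then draws one stratified
batch of 16 targets (one uniform draw per sixteenth of the range, so
the edges are always represented) and iterates in blocks of 5 until the
mean absolute endpoint error on the probe grid {4, 8, 12, 16, 20}° has
stopped improving by more than 0.05° for two consecutive blocks, or 8
blocks have run. The inverse-Hessian approximation persists across
epochs. Optionally the granule time constant and the spectral radius
join the parameter vector for a joint refinement, scaled by their
starting values so a unit step means a comparable relative change for
every coordinate, under box constraints (`tau` in 5–100 ms, `rho` in
(0, 1]) enforced by projection after each line-search step. The joint
phase starts from the trained readouts: a cold joint start greedily
drifts the reservoir parameters into a long-memory corner (`tau` at its
upper bound) from which the readout optimization cannot recover and
which ends at a visibly higher cost, whereas the warm-started search
settles at an interior optimum.
With the reference sizes (N = 100 per side, 1 ms steps, 0.4 s trials) a
full adaptation takes on the order of two minutes on one core.

## Calibration constants

Several pathway constants are not identifiable from the loop equations
and are treated as calibration variables, fixed once against the
qualitative physiology the model is meant to exhibit and never revisited
per experiment:

* `w_mf_cfn_contra = 0.25`, `w_mf_cfn_ipsi = 0.75` — the direct
  mossy-to-fastigial excitations. The asymmetry (stronger on the
  ipsilateral side) gives the net correction a component proportional
  to `-u`, a self-limiting drive term. It was chosen so that (i) the
  baseline-subtracted fastigial traces show the contralateral
  burst-then-pause and ipsilateral pause-then-burst orderings with an
  early-phase magnitude that grows with target size, and (ii) an
  unexpected burst-amplitude drop is partially compensated online (the
  intact-vermis speed reduction comes out smaller than the clamped one),
  the behaviour observed in primates with an intact vermis.
* `mf_gain = 0.3` — the scale of the normalized mossy channels
  (each first brought to [0, 1], the burst channel by the nominal
  amplitude `A` so vigor reductions remain visible). At gain 1 the
  drawn ±30 input weights push most granule units into saturation and
  the population responds almost binarily; at 0.3 a large fraction of
  units stays in the graded range, granule responses show the mixture
  of burst and pause shapes expected of the granular layer, and the
  Purkinje peak-change-versus-peak-speed relation becomes tightly
  linear.
* `f_max = 1` — the granule rate unit; it sets the scale of the readout
  weights (and hence of the penalty `γ||w||²`) but was found not to
  change the fitted behaviour over a 4-fold range.

## What the simulator emulates — and what it does not

All experiments run on model-generated trajectories; there is no
external data. The generator emulates the trial protocol of primate
saccade-adaptation experiments: randomly drawn rightward targets of
4–20°, movement onset detected at a 30 deg/s speed threshold, visual
(endpoint) error driving plasticity between trials, and a reduced-vigor
manipulation implemented as a 16% drop in burst amplitude. It does not
emulate: vertical or leftward saccades and the collicular topography
that would support them; spiking dynamics or trial-to-trial neural
noise (every trial is deterministic given the weights); proprioceptive
feedback; plant fatigue or long-term plant changes; or reward schedules
behind motivation. Passing tests therefore show that the control
architecture can produce the reported kinematic and population-activity
patterns, not that it quantitatively matches any particular animal.

## Numerical choices

* Fixed 1 ms Euler step for the reservoir (`dt < tau/10` at the
  defaults) and exact ZOH stepping for the plant; both well inside
  their stability regions. The tiny test configuration uses 2 ms.
* One-step (dt) feedback delay between the burst and its efference
  copy's effect on the correction, avoiding an algebraic loop.
* Reservoir state starts every trial at its relaxed fixed point under
  zero input (computed by integrating 40 τ, cached per `rho`); the
  fixed point is independent of `tau`.
* Movement onset is the first up-crossing of 30 deg/s; if the speed
  never crosses (degenerate weights), the hold fires at trial end and
  the trial is flagged.
* The quasi-Newton update is skipped when the curvature condition
  `s·y > 0` fails; directions that are not descent directions fall
  back to steepest descent.
* Ties in the bulge detector (identical speed traces) count as no
  bulge, so a zero-size perturbation yields no bulge on either side.

## Known limitations

* The fitted optimum uses a gentle drive with distributed braking
  rather than a maximal early burst followed by a hard stop. Some
  population-level timing consequences expected of the latter regime —
  in particular a Purkinje peak that precedes peak eye speed, and
  endpoint dysmetria of a couple of degrees when the vermal output is
  clamped under a 16% vigor drop — do not emerge from the
  error-minimizing solution of this loop (the clamped trial is partially
  rescued by the brainstem's internal feedback, whose burst persists
  while its displacement estimate lags). Injecting a hand-built
  early-burst solution and re-optimizing returns to the gentle-drive
  optimum at lower cost, so this is a property of the objective and
  architecture, not of the optimizer.
* Only the parallel-fiber-to-Purkinje weights adapt; there is no
  timing-dependent plasticity rule and no multiple-timescale
  adaptation.
* The displacement integrator resets between trials and its
  imperfection is purely the gain `k`; no leak dynamics are modelled.
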