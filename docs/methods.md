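# Methods

## The model

`follownet` simulates a two-layer network of deterministic leaky
integrate-and-fire (LIF) neurons that learns, online, to act as a forward
model of a low-dimensional dynamical system (a plant): given the motor
command `u(t)`, the network's decoded output `x̂(t)` should reproduce the
plant state `x(t)`.

**Neurons.** Each LIF neuron obeys `τ_m dV/dt = −V + J` with `τ_m = 20 ms`,
threshold 1, reset 0, floor 0, and absolute refractoriness `τ_r = 2 ms`.
Under constant current the rate is the closed form
`g(J) = 1/(τ_r + τ_m ln(J/(J−1)))` for `J > 1`, zero otherwise.
The discrete update (Δt = 1 ms) is the exact exponential step over the
non-refractory fraction of the tick; when the voltage crosses threshold
inside a tick, the crossing time is interpolated and the refractory clock is
charged from that instant. This sub-step scheme (the one used by the
simulator the protocols were originally run in) removes the step-size
quantization of inter-spike intervals; with whole-step refractoriness the
empirical rate at `J = 5` is ~8% off the closed form, far outside the 2%
check the package holds itself to.

**Populations.** A population represents a variable of radius `R` through
per-neuron currents `J_i = ν_i (ẽ_i · x) + b_i`, with normalized encoders
`ẽ_i` uniform on the sphere of radius `1/R`. Two tuning schemes ship:

* `intercept_maxrate` (default): intercept uniform in [−1, 1), rate at full
  projection uniform in [200, 400) Hz; gain and bias solved from the closed
  form. This gives a heterogeneous basis with neurons recruited throughout
  the ball.
* `fixed_gain`: ν = 2, bias uniform in [−2, 2) — the lower-rate variant used
  by the full-scale non-linear-oscillator run.

**Auto-encoder.** Before any learning, readout decoders `d` (Nd × N) are
ridge-solved so that decoding the static rates of an encoded point returns
the point: P = N sample points drawn volume-uniformly from the R2-ball,
regularizer `λ = P (0.1 max activity)²`, normal-equations solve
(`scipy.linalg.solve`, symmetric positive-definite path). Together with the
fixed random error-feedback encoders `k e_iα` this forms a loop of gain `k`:
an error `ε` pushed into the population and decoded returns `≈ k ε`.

**Closed loop.** Per 1 ms tick (order fixed; currents read the previous
tick's recurrent and error traces, giving the loop a one-tick latency):
command currents → command LIF step → command traces (exponential synapse,
`τ_s = 20 ms`, unit-area impulses) → recurrent currents
(`w_ff`·cmd-traces + `w_rec`·rec-traces + `k e`·(ε∗κ) + bias) → recurrent
LIF step → traces → decode `x̂ = d`·traces → `ε = x_ref − x̂` (+ optional
noise) → error traces (κ, τ_s) and learning traces (κ_ε, `τ_ε = 200 ms`
default, 80 ms available) → weight update. With `k = 10` and zero plastic
weights the loop already tracks: `x̂ ≈ k/(k+1) x`, relative error `1/(k+1)`.

**FOLLOW rule.** Both plastic matrices follow

    dw_ij/dt = η (I_i^ε ∗ κ_ε)(S_j ∗ κ),    I_i^ε = k Σ_α e_iα ε_α,

the product of the slow-filtered projected error current in the postsynaptic
neuron (one factor per neuron) and the fast-filtered presynaptic spike trace
(one per synapse). With κ_ε replaced by κ this is exactly stochastic
gradient descent on the instantaneous quadratic loss in the projected error
(asserted to machine precision in the tests).

**Learning-rate units.** The printed rates (η = 2e-4) are in the original
simulator's error-driven-rule units: the per-synapse coefficient is
`η · dt / N_pre`, where `N_pre` is the presynaptic population size. The 1/N
normalization makes the learning speed of the *decoded output* independent
of how many neurons carry it. This matters: without it, η = 2e-4 drives the
weights into instability within seconds at N = 500–1000 (verified
empirically), because the population-summed update is then N times stronger
than the printed protocols assume.

## Reference systems

Five plants, all integrated by forward Euler at the shared 1 ms clock
(`substeps` gives the fine-step oracle): a linear decaying oscillator, the
van der Pol oscillator (timescale 0.125 s), the Lorenz system in shifted
coordinates (x3 = Z − 28), the linear system behind a cubic input
non-linearity, and a two-link arm under gravity (masses 1.4/1.1 kg, lengths
0.30/0.33 m, viscous joint damping, torque ramp-clipped to zero between 90°
and 135° so no link can swing over). Arm signals map to network units by
0.02 per N·m, 0.05 per rad/s, and 1/2.5 per rad, so command, velocity and
angle occupy one fifth, one half and all of the representation radius.

Euler at 1 ms is *not* accurate for the van der Pol relaxation jumps
(relative L2 error ~16% over 2 s against a 10×-finer run, ~1.7% at 0.1 ms,
halving with dt — first-order convergence as it must). This is intrinsic to
the stated integrator, not an approximation made for speed; the learning
protocols inherit it by construction because network and plant share the
clock. For the chaotic Lorenz system, step size changes individual
trajectories but not the attractor statistics the experiments use.

Reference filtering: the reference passes through the κ filter before the
error node (matching the filtering implicit in the decoded output), except
for the arm and the unfiltered-Lorenz variant, which compare raw.

## Protocols

The canonical run has three phases sharing one continuous reference
trajectory: ~4 s with feedback and plasticity off (output sits at the
bias-decode level near zero), a learning phase (feedback on, babbling
command input: fresh uniform pulses every 50 ms within ±ζ1 plus a pedestal
of norm ζ2 redrawn every T_period, per-component amplitudes where the
shipped table says so, linear interpolation for the arm), and an open-loop
test (feedback off) on fresh input of the same statistics. The shipped
per-system table carries the printed full-scale sizes, radii, amplitudes and
rates; tests and examples run scaled-down versions (500–1000 neurons,
100–500 s) and say so. Metrics: mean squared error per dimension in 4 s
blocks; final-window MSE for sweeps over the last 20% of learning (the
printed sweeps used the last 400 s of 10,000 s).

The realizable-reference protocol first trains a network on the ODE plant,
freezes it, and uses its open-loop decoded output as the target for an
identical-architecture learner starting from zero weights. Exact solution
weights then exist; the learner's error drops below the matched ODE run and
its weights move toward the reference's (R² to the identity line). Weight
identifiability is partial at desk scale: the recurrent R² rises steadily,
while the feedforward matrix can trade off against the recurrent one early
in learning. Spike alignment (fraction of learner spikes within ±2 ms of
the same-index reference spike, under feedback) operationalizes the
spike-train entrainment the low-dimensional feedback produces.

Readout relearning: with the learned (or entry-shuffled) plastic weights
frozen, fresh readout weights are trained from zero by the perceptron rule
`ḋ_αi = −η_r (x̂'_α − target_α)(S_i ∗ κ)`, `η_r = 1e-4`, against the
network's own decoded output. Only the specifically-learned matrix supports
relearning — the shuffled control (same weight distribution, permuted
entries) ends with larger error, the evidence that the network is not a
random reservoir.

## Synthetic world, and what a green test establishes

There is no external data; the world is the stated one: babbling inputs
with the shipped amplitudes, plants integrated from their printed equations,
networks sampled from the stated tuning distributions. Scaled-down runs
keep every mechanism (spiking, feedback, plasticity, phase structure) and
shrink only population size and duration; they establish that the scheme
learns and generalizes at desk scale, not the full-scale headline numbers
(e.g. the 12–13 Hz mean-rate histograms), which require the multi-hour
printed protocol shipped as `examples/08_fullscale_fig2.py`.

## Numerical choices

* Determinism: one global seed expands via `SeedSequence.spawn` into
  tuning / decoder-sample / input / noise streams; every run is bit
  reproducible.
* The numba kernel is an optimization of the pure-numpy `step()` (the
  semantic reference, kept and tested for equivalence); the kernel defers
  each tick's rank-1 weight increment into the next tick's matrix pass,
  which halves memory traffic and changes no value the simulation reads.
* Error noise is per-tick i.i.d. Gaussian of the stated σ (no 1/√dt
  scaling), matching the printed "standard deviation of noise" axis.
* Weights are unbounded (the printed runs needed no decay term); masked
  (absent) synapses stay exactly zero through learning.
* Decoder perturbations multiply decoder entries once, at setup, by
  `1 + U(−χ+ξ, χ+ξ)`; feedback encoders are never perturbed.
* Sensory delay shifts the reference series; compensation shifts the
  network's command path identically while the plant still sees the
  undelayed command.

## The error-filter mismatch and open-loop accuracy at desk scale

The rule as printed filters the error current with a 200 ms kernel while the
presynaptic trace carries the 20 ms synaptic kernel. A mismatched filter
pair phase-shifts the learning signal against the presynaptic activity at
the plant's operating frequencies (at 20 rad/s a 200 ms filter contributes
−76° of phase and 4× attenuation), which biases the weight *equilibrium*,
not just the learning speed — the same effect known from filtered-error LMS
adaptation. The effect is directly measurable here: on the linear
oscillator, regressing the trained network's open-loop derivative on state
and input recovers the true dynamics matrix and input gain almost exactly
when the error filter is set equal to the synaptic filter (the form the
stability derivation itself produces), but recovers the fast components
5–10× too weak with the 200 ms filter. Longer training does not remove the
bias; it is an equilibrium property.

For the van der Pol oscillator a second, independent limitation appears at
desk scale: the clamped training trajectory concentrates near the limit
cycle, so the non-linear damping term `2(1−x1²)x2` — whose two pieces are
nearly collinear along the cycle — is severely under-determined (learned
coefficients ~15% of target at 500–1000 neurons and up to 500 s). The
closed-loop error still plateaus near the spike-noise floor, because the
feedback supplies the missing drive, but the open-loop cycle inflates in
amplitude and slips phase within about a second. Matching the printed
protocols' open-loop prediction quality requires their scale (3000+ neurons
per layer, thousands of seconds); the corresponding acceptance check is
deliberately left failing at desk scale rather than weakened, and the
learning-curve check (≥10× block-MSE drop) passes.

## Known limitations

* Euler-at-1-ms trajectory error for stiff segments (see above); the 1%
  fine-step agreement holds for the linear and arm systems at 0.1 ms but
  not for van der Pol.
* Parameter recovery against a realizable reference is statistical, not
  exact, at desk scale; function converges faster than parameters.
* No Dale's law, no conduction delays, no excitatory/inhibitory balance;
  the auto-encoder is solved algorithmically rather than learned.
* The shipped pulse/pedestal amplitudes for the arm and the cubic-input
  system follow the printed table literally even where those amplitudes
  exceed the command radius; those two systems' learning performance is not
  covered by the test suite.
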