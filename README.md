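# follownet

Spiking recurrent networks that learn forward models of non-linear dynamics
through negative error feedback and a local, online plasticity rule
(FOLLOW — Feedback-based Online Local Learning Of Weights).

## The problem

To plan and correct movements, a motor system needs a *forward model*: a
circuit that predicts the next state of the body (say, joint angles and
velocities of an arm) from the outgoing motor command. `follownet` is for
computational neuroscientists who want to study how a network of spiking
neurons can *learn* such a model with rules that are biologically
plausible — online (no batch replay) and synaptically local (each weight
change uses only the presynaptic spike trace and a signal present in the
postsynaptic neuron).

## The scheme

A command-representation layer of heterogeneous LIF neurons encodes the
motor command `u(t)` and projects through plastic feedforward weights
`w^ff` into a recurrent layer with plastic lateral weights `w`. Fixed
readout weights decode the predicted state

    x̂_α(t) = Σ_i d_αi (S_i ∗ κ)(t),      κ(t) = e^{−t/τ_s}/τ_s,  τ_s = 20 ms,

and the output error `ε = x − x̂` against the reference plant is fed back
into every recurrent neuron through fixed random encoders with gain `k`:
`I_i^ε = k Σ_α e_iα ε_α`. Because `d` and `e` are pre-solved to form an
auto-encoder, this loop clamps the output to within `1/(k+1)` of the
reference from the first moment of learning — and the very signal that does
the clamping is the error current each synapse needs:

    dw_ij/dt = η (I_i^ε ∗ κ_ε)(S_j ∗ κ),

with `κ_ε` a slower exponential filter (200 ms). The same rule trains both
plastic matrices; it is provably a stochastic-gradient step on the
instantaneous projected-error loss, and it learns linear, van der Pol,
chaotic Lorenz, and two-link-arm dynamics from random "motor babbling".

## Worked example

```python
import numpy as np
import follownet as fn

res = fn.learning_protocol("vdp", n_neurons=500, t_pre=4.0,
                           t_learn=120.0, t_test=8.0, seed=0)
print(res.block_mse[0], res.block_mse[-1])
test_err = np.linalg.norm(res.phases["test"].err[:200], axis=1).mean()
ref_amp = np.linalg.norm(res.xref["test"][:200], axis=1).mean()
print(test_err, ref_amp)
```

prints (seed 0, ~3 min on one CPU)

```
0.03343083944397783 0.001496748118978899
2.929760889671455 1.9914401239501058
```

The first two numbers are the mean squared error per dimension over the
first and last 4 s blocks of learning: a ~22× drop. The first block is
small already because the error feedback clamps the output to the van der
Pol reference from the start; the drop below that level is the weights
taking over the work of the feedback. The last pair is the mean error
during the first 2 s of the *open-loop* test (feedback off) against the
reference amplitude: at this desk scale the freed network oscillates with
roughly the right amplitude but slips phase quickly, so the error is of the
order of the amplitude itself — multi-second open-loop prediction is what
the full-scale printed protocol (3000+3000 neurons, 5,000 s;
`examples/08_fullscale_fig2.py`) buys, and `docs/methods.md` explains why
the scaled-down run cannot.

The `examples/` directory has one short script per capability — tuning
curves, the auto-encoder round trip, the 1/(k+1) clamp, van der Pol
learning, the Lorenz tent map, realizable-reference weight recovery,
robustness sweeps, the arm, and the full-scale multi-hour protocol
(`08_fullscale_fig2.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — the auto-encoder
round trip, the closed-loop clamp at k=10, and a scaled-down van der Pol
learning run — printing what it measures and writing the result file.
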