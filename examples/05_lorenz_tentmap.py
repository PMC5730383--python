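"""The Lorenz attractor and its tent map from the reference integrator.

The chaotic Lorenz system (in coordinates shifted so all observables vary
around zero: x3 = Z - 28) is kicked once for 250 ms and then runs
autonomously.  Successive local maxima of x3 trace the classic single-humped
tent return map — the signature used to compare a trained network's attractor
against the true one.
"""

import numpy as np

import follownet as fn

spec = fn.make_reference("lorenz")
u = fn.lorenz_kick(3.0, 120.0, 1e-3, np.random.default_rng(0))
x = fn.integrate_reference(spec, u, 1e-3)

print(f"trajectory over {x.shape[0] / 1000:.0f} s:")
print(f"  x1 range [{x[:, 0].min():6.2f}, {x[:, 0].max():6.2f}]")
print(f"  x3 range [{x[:, 2].min():6.2f}, {x[:, 2].max():6.2f}] "
      f"(Z stays positive: min Z = {(x[:, 2] + 28).min():.2f})")

pairs = fn.tent_map(x[5000:, 2])
print(f"\ntent map: {len(pairs)} consecutive-maxima pairs")
top = pairs[:, 0].argsort()
mid = pairs[len(pairs) // 2]
print(f"  example pair: max_n = {mid[0]:.2f} -> max_n+1 = {mid[1]:.2f}")
print(f"  peak of the map sits at max_n ~ "
      f"{pairs[pairs[:, 1].argmax(), 0]:.1f} (interior hump: low maxima map "
      "up, high maxima map down — the stretch-and-fold of the attractor)")
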