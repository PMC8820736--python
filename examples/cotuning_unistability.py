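"""Co-tuned inhibition widens the uni-stable parameter regime.

For N interacting ensembles, the block Jacobian's differential modes decide
whether the symmetric baseline is the only attractor. Co-tuning (m < 1)
strictly lowers the leading differential eigenvalue, enlarging the
uni-stable region of the (a, d) phase plane.
"""

import numpy as np

from ntanet import presets as P
from ntanet.ensembles import simulate_two_ensembles_from_table, unistability_map

grid = unistability_map(np.linspace(0, 200, 41), np.linspace(0, 200, 41), k=0.1, m=0.5)
n_global = int(grid["global"].sum())
n_cotuned = int(grid["cotuned"].sum())
print(f"uni-stable grid points, global inhibition:   {n_global}")
print(f"uni-stable grid points, co-tuned inhibition: {n_cotuned}")
print(f"the global set is a subset of the co-tuned set: "
      f"{bool(np.all(~grid['global'] | grid['cotuned']))}\n")

g = P.default_gain()
for label, multistable in (("multistable (JEE=1.4)", True), ("uni-stable (JEE=1.3)", False)):
    net = simulate_two_ensembles_from_table(
        P.two_ensemble_populations(multistable), g, P.default_std(), duration=8.0, seed=3
    )
    post = net.r_e[(net.t >= 7.0) & (net.t < 8.0)].mean(axis=0)
    print(f"{label}: post-stimulus ensemble rates = "
          f"({post[0]:.3f}, {post[1]:.3f}) Hz")
print("\nThe multistable network keeps an asymmetric persistent state after the")
print("stimulus; the uni-stable one relaxes back to the symmetric baseline.")
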