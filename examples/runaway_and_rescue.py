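"""Stabilization trichotomy of a single supralinear ensemble.

The ensemble (JEE=1.8, JEI=1.0, JIE=1.0, JII=0.6, quadratic gains) has
det(J) < 0, so a strong enough drive removes all fixed points: the plain
model blows up. Spike-frequency adaptation can only trade the blow-up for
an oscillation, while either form of short-term plasticity quenches the
onset transient into a stable stimulated state and returns to baseline.
"""

import numpy as np

from ntanet import presets as P
from ntanet.params import StimulusProtocol
from ntanet.rate import simulate_ensemble
from ntanet.sfa import classify_sfa_dynamics
from ntanet.protocols import STRONG_SFA_B

w, rp, g = P.single_ensemble_weights(), P.single_ensemble_rate_params(), P.default_gain()
protocol = StimulusProtocol.step(2.0, 4.0, dg_e=3.0 - 1.55)  # gE: 1.55 -> 3.0

plain = simulate_ensemble(w, rp, g, protocol=protocol, duration=6.0)
print(f"plain supralinear ensemble: diverged={plain.diverged} "
      f"at t={plain.divergence_time:.3f} s (finite-time runaway)")

sfa = classify_sfa_dynamics(w, rp, g, P.default_sfa(STRONG_SFA_B), protocol)
print(f"strong SFA (b={STRONG_SFA_B:g}): {sfa.label} at "
      f"{sfa.oscillation_frequency:.1f} Hz (no stable stimulated state)")

for name, mech in (("E-to-E STD", P.default_std()), ("E-to-I STF", P.default_stf())):
    traj = simulate_ensemble(w, rp, g, mech, protocol, duration=6.0)
    sel = (traj.t >= 2.0) & (traj.t < 4.0)
    mid = (traj.t >= 2.5) & (traj.t < 3.5)
    base = (traj.t >= 1.5) & (traj.t < 2.0)
    print(f"{name}: onset peak {traj.r_e[sel].max():.0f} Hz, stimulated fixed point "
          f"{traj.r_e[mid].mean():.2f} Hz, baseline {traj.r_e[base].mean():.3f} Hz, "
          f"post-stimulus {traj.r_e[traj.t >= 5.5].mean():.3f} Hz")

# The onset peak is the amplification: peak/input vastly exceeds the
# linear network's ratio with the same weights.
print("\nThe onset transient amplifies the stimulus by orders of magnitude while")
print("the network still settles into a low, stable state and returns to baseline.")
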