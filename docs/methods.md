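# Methods

## Model

The core object is a neuronal ensemble of one excitatory (E) and one
inhibitory (I) population with rectified power-law (supralinear) gains:

    tau_E drE/dt = -rE + [JEE rE - JEI rI + gE]_+^alphaE
    tau_I drI/dt = -rI + [JIE rE - JII rI + gI]_+^alphaI

Weights are magnitudes (signs live in the equations); the default exponents
are alphaE = alphaI = 2 and the default time constants tau_E = 20 ms,
tau_I = 10 ms. The determinant of the signed weight matrix,
det(J) = -JEE·JII + JIE·JEI, decides whether the ensemble can generate
positive-feedback dynamics: with det(J) < 0 there is a critical excitatory
drive gE* above which all fixed points vanish and activity runs away in
finite time. The bifurcation structure is analyzed through the
characteristic function F(z) — a one-dimensional reduction in the total
excitatory input current z whose zero crossings are the fixed points, found
by a dense scan (a fine linear grid on the rectified branch plus a geometric
tail, with adaptive extension of the upper limit until the tail behavior is
settled) followed by bisection; roots map back to rates in closed form and
are classified by the 2x2 Jacobian's eigenvalues. The critical input is
located by bisection on the fixed-point count, which is monotone because F
shifts upward with gE.

Three activity-dependent mechanisms can be attached:

* **SFA** — an adaptation current a with `tau_a da/dt = -a + b·rE`
  subtracted from the E drive (defaults tau_a = 200 ms; b = 1 is the weak
  published value).
* **E-to-E STD** — a resource x in (0, 1] with
  `dx/dt = (1-x)/tau_x - Ud·x·rE` multiplying JEE (tau_x = 200 ms, Ud = 1).
* **E-to-I STF** — an efficacy u in [1, u_max] with
  `du/dt = (1-u)/tau_u + Uf·(u_max-u)·rE` multiplying JIE
  (tau_u = 200 ms, Uf = 1, u_max = 6).

Closed-form steady states `x* = 1/(1 + Ud·rE·tau_x)` and
`u* = (1 + Uf·u_max·rE·tau_u)/(1 + Uf·rE·tau_u)` serve as simulation
cross-checks. STD analysis includes the depressed-weight characteristic
function (JEE -> x·JEE, which can flip the sign of the effective
determinant and with it the curvature of F), the 3x3 Jacobian and its
cubic characteristic polynomial, the ISN index (leading eigenvalue of the
frozen-inhibition (rE, x) block) and the paradoxical-effect condition
`x > 1/(JEE·alphaE·rE^((alphaE-1)/alphaE))` together with the
nullcline-slope ordering, which we evaluate explicitly instead of assuming
it. With these definitions the paradoxical region of the (JEE, x) plane is
contained in the ISN region: a paradoxical response is sufficient but not
necessary for inhibition stabilization.

## Numerical integration

All rate (and spiking) dynamics use fixed-step explicit Euler at
dt = 0.1 ms, in seconds internally. Rates are clipped at zero after each
step (SFA can transiently push the Euler update negative because the
adaptation current acts outside the rectification); x and u are clipped to
their invariant ranges to absorb Euler overshoot. Runaway is genuine in
this model class, so integration stops cleanly once rE exceeds a
configurable bound (default 1e6 Hz) and the trajectory is flagged
diverged; NaN/overflow is likewise flagged, never raised. Halving dt
changes converged final states by < 1e-3 (tested).

Two regimes deserve comment. First, with E-to-E STD and inhibition
inactivated, the model possesses a stable high-rate fixed point
(~137 Hz for the canonical parameters) but reaches it only after an
enormous finite transient excursion (the depression variable lags the
explosive rate growth); under the default divergence bound that bounded
trajectory would be misclassified, so the no-inhibition comparison runs
unbounded and assesses finiteness — the facilitating network, which has no
fixed point at all without inhibition, genuinely overflows. Second, strong
SFA captures the stimulated runaway into a large relaxation limit cycle
(~30 Hz for b = 300) that coexists with a locally stable low-rate fixed
point; the textbook Hopf sign change of tr·(A11+A22+A33) - det does occur
along the drive axis (exposed as `sfa_hopf_margin_curve`), but at the
canonical drive the oscillation is the relaxation cycle, not the small
local one. The "strong" b = 300 default was chosen once as the first
decade of a coarse multiplier sweep on the published b = 1 at which
stimulation yields a sustained oscillation instead of runaway.

## Multi-ensemble theory and simulations

For N symmetric ensembles the Jacobian is assembled from gain-scaled
couplings a, b, c, d (weights times the gain slope at a common operating
point, divided by the time constant), leak rates e = 1/tau_E, f = 1/tau_I,
an inter-ensemble excitation factor k and a co-tuning degree m in [0, 1]
(m = 1: one global inhibitory pool; m = 0: fully ensemble-specific
inhibition). The spectrum has four distinct eigenvalues, two of
multiplicity N-1 (ensemble-differential modes) and two of multiplicity 1
(common modes, identical between variants). Uni-stability — a single
symmetric attractor — requires the leading real part to be negative;
co-tuning strictly lowers the differential eigenvalue, so the
global-inhibition uni-stable set is contained in the co-tuned one. The
default phase diagram uses k = 0.1, m = 0.5, b·c = 0.9·a·d, e = 50/s,
f = 100/s on a, d in [0, 200] (the published scan states the first three;
the leak rates follow from the canonical time constants, and the grid
bounds were chosen to bracket both stability boundaries).

Concrete two-ensemble networks come in two flavors: a population-level
four-population network (the attractor demonstrations: within-ensemble
JEE = 1.4 gives multi-stability, 1.3 uni-stability, both with E-to-E STD
and a seeded 1e-3 uniform initial perturbation to break symmetry), and a
neuron-normalized microcircuit of 2 x (100 E + 25 I) all-to-all connected
neurons whose per-connection weights are the published totals divided by
the fan-in. Identical neurons are grouped into populations, so subset
stimulation (75%/25% of ensemble 1) is simulated exactly by splitting E1
into two subpopulations with per-connection weights preserved. Pattern
completion is quantified by the association index
`1 + (rE12 - rE11)/(rE12 + rE11)` (0-1 in the partial-completion regime),
selectivity by the distance of (rE1, rE2) to the symmetric decision
boundary — the degree-based formula is algebraically |x-y|/sqrt(2) and is
tested against that identity — and amplification by the peak/input ratio.
Onset peaks are window maxima (ties to the earliest time); fixed points
average the middle 1 s of the 2 s stimulation window; baselines average
the preceding second.

## Spiking network

The spiking model is a conductance-based LIF network: membrane
`tau_m dU/dt = (Urest - U) + g_exc (Uexc - U) + (g_inh + a)(Uinh - U)`,
g_exc = xi·g_ampa + (1-xi)·g_nmda with the NMDA trace low-pass filtering
the AMPA conductance, and a GABA conductance; a presynaptic spike adds the
synaptic weight to the postsynaptic AMPA (GABA) conductance. E-to-E
synapses depress (x per presynaptic neuron, full-depletion jumps
x -> x - Ud·x) and E-to-I synapses can facilitate; SFA is an
inhibitory-reversal conductance bumped by b on the neuron's own spikes.
Published parameters: 20% random connectivity (no self-connections),
Urest = -70 mV, Uexc = 0, Uinh = -80 mV, tau_ref = 3 ms, tau_m = 20/10 ms
(E/I), tau_ampa = 5 ms, tau_gaba = 10 ms, tau_nmda = 100 ms, xi = 0.5, and
the within/inter-ensemble weight table; a synapse counts as
within-ensemble when pre- and postsynaptic neurons share at least one
ensemble. Each neuron receives independent external drive equivalent to
300 Poisson sources at 0.1 Hz (0.5 Hz for stimulated-ensemble members),
aggregated into per-step Poisson counts.

Two quantities are not published and are configuration fields: the spiking
threshold (default -50 mV) and the external synaptic weight (default 0.8,
calibrated once for a low spontaneous baseline of ~0.05-0.1 Hz with
reliable ensemble ignition at the published stimulation rate). The network
size is printed inconsistently in the source material (400/100 in the
parameter table, 800/200 in the prose); the canonical protocol defaults to
800 E / 200 I because at 400 the five 200-neuron ensembles overlap
pairwise by ~50%, which mechanically destroys the stimulated-vs-
unstimulated activity contrast the protocol is meant to exhibit. Both
sizes are a constructor argument.

Ensemble activity is the population rate in 10 ms bins. The PCA analysis
bins each excitatory neuron's spikes (10 ms by default), mean-centers per
neuron and reports explained-variance fractions. The first-two-PC fraction
is strongly bin-size dependent because raw 10 ms counts are dominated by
Poisson noise: with the canonical protocol it is ~0.20-0.24 at 10 ms,
~0.34 at 20 ms and ~0.55 at 50 ms, essentially independent of seed and of
the calibration knobs. The reported reference value of roughly 40% is
consistent with an analysis bin in the 25-50 ms range; we keep 10 ms as
the default for consistency with the ensemble-activity bin and report the
resulting fraction as-is.

## What the synthetic protocols do and do not show

All inputs are parameter sets plus internally generated Poisson spike
trains; there is no recorded data. The protocols demonstrate mechanisms —
threshold-gated transient amplification, re-stabilization by short-term
plasticity, the non-ISN -> ISN transition, the benefit of co-tuned
inhibition — under idealized conditions: homogeneous populations,
instantaneous synapses in the rate models, no delays, no heterogeneity, no
structured noise. Passing tests therefore validate the mathematics and the
implementation, not the biological magnitudes; in particular the uncapped
supralinear gain produces onset peaks (10^4 Hz and beyond) that in real
tissue correspond to brief, precisely timed spikes rather than sustained
rates, and the optional 300 Hz rate cap shows the qualitative picture
survives saturation.

## Known limitations

* Explicit Euler only; the STD-without-inhibition excursion is stiff and
  is reported as the scheme produces it (bounded, but with extreme
  transients) rather than through an adaptive solver.
* The E-to-I STF ISN/paradoxical algebra is not re-derived; facilitating
  networks are assessed by numerical probes only.
* The multi-ensemble eigenvalue theory linearizes at a symmetric operating
  point and ignores short-term plasticity; its uni-stability verdicts are
  local statements, checked against perturbation growth in matching
  rectified-linear networks rather than global attractor counts (corner
  attractors of rectified systems are outside the theory).
* Basins of attraction, storage capacity at many ensembles, and synaptic
  delays are out of scope.
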