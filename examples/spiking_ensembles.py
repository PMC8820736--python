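"""Transient amplification in a conductance-based spiking network.

Five overlapping 200-neuron ensembles in a randomly connected LIF network
with depressing E-to-E synapses are stimulated in turn by raising their
external Poisson rate from 0.1 to 0.5 Hz per source. Ensemble onset
responses tower above the subsequent fixed-point activity. (~25 s runtime
for the 10 s protocol shown here.)
"""

from ntanet.protocols import protocol_spiking_ensembles

result = protocol_spiking_ensembles(seed=7, duration=10.0)
for d in result["differences"]:
    print(f"ensemble {d['ensemble']}: onset activity difference "
          f"{d['onset_diff']:.1f} Hz vs fixed-point difference "
          f"{d['fixedpoint_diff']:.1f} Hz")
print(f"\nfirst two PCs capture {100 * result['pca_first_two']:.1f}% of the "
      "variance of the binned excitatory spiking (10 ms bins, first 10 s)")
print("The onset transient separates the stimulated ensemble from the rest far")
print("better than the fixed point, as in the rate models.")
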