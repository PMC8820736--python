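"""Stimulus-induced transition into the inhibition-stabilized regime.

With E-to-E depression the ensemble starts as a non-ISN at baseline and
becomes an ISN while stimulated: the ISN index (leading eigenvalue of the
frozen-inhibition subsystem) flips sign, and injecting excitatory current
into the inhibitory population then *lowers* its rate (paradoxical effect).
"""

from ntanet.protocols import protocol_isn_timecourse

result = protocol_isn_timecourse()
print(f"ISN index at baseline:   {result['baseline_index']:+.2f} 1/s  (non-ISN)")
print(f"ISN index during stim:   {result['stim_index']:+.2f} 1/s  (ISN)")
print(f"extra drive to I, baseline: rI change {result['baseline_probe_drI']:+.4f} Hz")
print(f"extra drive to I, stimulus: rI change {result['stim_probe_drI']:+.4f} Hz "
      "(paradoxical: inhibition drops)")
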