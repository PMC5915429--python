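# Secondary-structure weight applied to the expected residue density
# (H = helix, E = strand, C = coil). Neutral by default; edit to supply
# calibrated weights.
H	1.0
E	1.0
C	1.0
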