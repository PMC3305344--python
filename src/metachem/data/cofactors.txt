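# Default cofactor / currency metabolite names discarded before reaction
# pairing. One name per line; edit freely.
ATP
ADP
AMP
NAD+
NADH
NADP+
NADPH
FAD
FADH2
CoA
Pi
PPi
H2O
CO2
O2
NH3
H+
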