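# linear chain used to demonstrate the anti-overselection term
[metabolites]
A
[biomass]
consume
[reactions]
uptake	0	0	10	A:1.0
consume	0	0	20	A:-1.0
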