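# two parallel routes from A to B; the leaky route loses 10% of carbon,
# so the reference optimum saturates the direct route first
[metabolites]
A
B
[biomass]
consume
[reactions]
uptake	0	0	10	A:1.0
direct	0	0	6	A:-1.0	B:1.0
leaky	0	0	10	A:-1.0	B:0.9
consume	0	0	20	B:-1.0
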