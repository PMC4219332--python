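# two routes into B; the alternative route burns 2 A per unit, so the
# reference optimum saturates the main route and barely uses the other.
# Inhibiting the main route makes the adjustment reroute through "alt",
# i.e. up-regulates it.
[metabolites]
A
B
[biomass]
consume
[reactions]
uptake	0	0	10	A:1.0
main	0	0	7	A:-1.0	B:1.0
alt	0	0	5	A:-2.0	B:1.0
consume	0	0	20	B:-1.0
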