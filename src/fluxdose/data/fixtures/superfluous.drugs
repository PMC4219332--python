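# narrow's targets are a strict subset of broad's; at the optimum the
# narrow drug is superfluous and must come back with zero dosage
narrow	targets=consume
broad	targets=uptake,consume
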