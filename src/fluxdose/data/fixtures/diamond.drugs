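# one drug on the direct route; inhibition forces rerouting via the leaky path
d1	targets=direct
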