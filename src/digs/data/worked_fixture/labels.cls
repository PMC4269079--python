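9 3 1
# c1 c2 c3
c1 c1 c1 c2 c2 c2 c3 c3 c3
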