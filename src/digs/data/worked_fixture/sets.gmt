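PW01	synthetic pathway	g0001	g0002	g0003
PW02	synthetic pathway	g0004	g0005	g0006	g0007	g0008
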