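component,weight
1,0.770
2,0.140
3,0.09
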