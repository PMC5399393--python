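pathway	hits	term_size
eNOS signaling	4	135
Gap junction signaling	4	151
Axonal guidance signaling	5	427
Glucocorticoid receptor signaling	4	272
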