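Model,Precision,Accuracy
A1,75.1,74.5
A2,72,71.3
A3,83.6,82.9
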