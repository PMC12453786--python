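Model,Precision,Accuracy
A1,D,D
A2,BD,BD
A3,ND,ND
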