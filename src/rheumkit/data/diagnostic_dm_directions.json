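{
 "Precision": "benefit",
 "Recall": "benefit",
 "F-score": "benefit",
 "Kappa": "benefit",
 "Hamming loss": "cost",
 "MCC": "benefit",
 "Accuracy": "benefit"
}
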