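Model,train_mean,validation_mean
XGBoost,0.9998,0.8295
KNN,0.7943,0.6883
DT,1,0.7976
RF,1,0.8337
SVM,0.7244,0.7214
ANN,0.7945,0.7749
SGD,0.6353,0.6359
GBoost,0.9174,0.841
LGBM,1,0.8334
AdaBoost,0.3576,0.3524
NB,0.59,0.5887
ET,1,0.8127
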