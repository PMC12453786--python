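Model,train_mean,validation_mean
XGBoost,0.9999,0.8542
KNN,0.8035,0.7167
DT,1.0,0.8218
RF,1.0,0.861
SVM,0.7478,0.7417
ANN,0.8144,0.7999
SGD,0.6207,0.618
GBoost,0.9237,0.8628
LGBM,1.0,0.861
AdaBoost,0.3931,0.3933
NB,0.6395,0.6386
ET,1.0,0.852
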