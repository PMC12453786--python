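Model,Precision,Recall,F-score,Kappa,Hamming loss,MCC,Accuracy
XGBoost,ND,ND,SD,SD,ND,SD,ND
KNN,BD,BD,BD,BD,D,BD,BD
DT,SD,SD,SD,SD,ND,SD,SD
RF,ND,SD,ND,ND,ND,ND,ND
SVM,D,BD,BD,D,SD,D,SD
ANN,D,SD,SD,SD,ND,SD,SD
SGD,SD,D,D,D,SD,D,SD
GBoost,ND,ND,ND,ND,ND,ND,ND
LGBM,SD,ND,ND,ND,ND,SD,ND
AdaBoost,HD,HD,HD,HD,HD,HD,HD
NB,D,D,BD,BD,BD,BD,BD
ET,ND,SD,SD,SD,ND,SD,ND
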