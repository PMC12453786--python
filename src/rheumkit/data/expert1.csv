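Model,Precision,Recall,F-score,Kappa,Hamming loss,MCC,Accuracy
XGBoost,ND,SD,SD,SD,ND,SD,ND
KNN,BD,BD,D,BD,D,BD,BD
DT,SD,D,SD,SD,ND,SD,SD
RF,ND,SD,ND,ND,ND,ND,ND
SVM,BD,BD,D,D,SD,D,D
ANN,SD,BD,SD,SD,ND,SD,SD
SGD,D,D,D,D,SD,D,D
GBoost,ND,ND,ND,ND,ND,ND,ND
LGBM,ND,SD,ND,SD,ND,SD,ND
AdaBoost,HD,HD,HD,HD,HD,HD,HD
NB,D,BD,BD,BD,BD,BD,BD
ET,ND,D,SD,SD,ND,SD,ND
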