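Model,Precision,Recall,F-score,Kappa,Hamming loss,MCC,Accuracy
XGBoost,ND,ND,ND,SD,ND,SD,ND
KNN,D,D,D,BD,D,BD,D
DT,SD,ND,SD,SD,ND,SD,SD
RF,ND,SD,ND,ND,ND,ND,ND
SVM,D,D,D,D,SD,D,SD
ANN,SD,SD,SD,SD,ND,SD,SD
SGD,SD,SD,D,D,SD,D,SD
GBoost,ND,ND,ND,ND,ND,ND,ND
LGBM,SD,ND,ND,SD,SD,ND,ND
AdaBoost,HD,HD,HD,HD,HD,HD,HD
NB,SD,D,BD,BD,BD,BD,BD
ET,ND,SD,SD,SD,ND,SD,ND
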