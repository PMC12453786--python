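Model,Precision,Recall,F-score,Kappa,Hamming loss,MCC,Accuracy
XGBoost,83.193,81.034,81.855,78.692,17.761,78.733,82.239
KNN,62.539,61.986,61.776,58.851,34.28,58.966,65.72
DT,78.864,78.769,78.782,75.554,20.436,75.564,79.564
RF,86.025,80.513,82.278,80.168,16.464,80.291,83.536
SVM,62.785,64.669,63.48,65.729,28.351,65.957,71.649
ANN,78.01,76.805,77.344,75.563,20.381,75.571,79.619
SGD,71.887,71.157,68.581,66.583,27.91,67.8,72.09
GBoost,86.544,82.036,83.543,80.665,16.078,80.78,83.922
LGBM,83.449,81.445,82.216,79.122,17.402,79.165,82.598
AdaBoost,21.98,38.78,25.173,24.721,62.355,28.626,37.645
NB,70.559,60.116,57.004,50.41,41.975,52.978,58.025
ET,83.014,76.535,77.98,77.462,18.698,77.591,81.302
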