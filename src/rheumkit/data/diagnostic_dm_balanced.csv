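Model,Precision,Recall,F-score,Kappa,Hamming loss,MCC,Accuracy
XGBoost,86.497,86.226,86.313,83.628,13.869,83.647,86.131
KNN,72.007,71.093,70.653,65.95,28.726,66.456,71.274
DT,83.649,83.515,83.574,79.875,17.061,79.878,82.939
RF,86.228,85.563,85.595,83.059,14.328,83.177,85.672
SVM,75.118,73.77,73.26,69.478,25.741,69.984,74.259
ANN,83.368,82.166,82.268,78.433,18.232,78.726,81.768
SGD,74.089,69.201,65.94,62.855,31.206,64.452,68.794
GBoost,87.347,86.78,86.802,84.511,13.111,84.624,86.889
LGBM,86.204,86.01,86.035,83.387,14.076,83.414,85.924
AdaBoost,36.71,33.099,21.684,21.255,65.603,26.015,34.397
NB,75.45,64.953,61.846,56.775,37.015,58.783,62.985
ET,86.309,85.309,85.634,82.689,14.65,82.73,85.35
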