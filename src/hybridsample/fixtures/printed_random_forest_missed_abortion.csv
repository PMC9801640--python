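Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,76.0,76.9,78.0,73.5,84.3,84.0,83.8,81.8,76.0,93.0,63.4,75.5,98.2
Sensitivity,50.0,64.9,72.3,69.6,79.1,79.1,79.1,60.7,50.0,86.6,53.6,68.7,93.9
Specificity,89.2,86.3,83.1,77.1,88.8,88.4,88.0,92.7,89.2,98.2,72.3,81.5,100.0
F-measure,75.9,75.4,77.6,73.3,83.9,83.7,83.5,81.1,75.9,92.4,62.6,75.0,98.1
MCC,43.0,52.5,55.8,46.9,68.2,67.8,67.3,58.1,43.0,85.4,26.4,50.4,95.4
AUC,74.5,81.6,82.2,80.0,86.9,86.0,87.2,82.6,74.5,93.8,57.9,81.2,99.9
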