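Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,76.0,77.1,78.5,74.7,83.7,84.3,83.9,82.1,78.6,93.0,65.6,75.9,98.2
Sensitivity,50.0,66.1,72.3,70.9,79.9,79.1,80.3,61.6,58.0,86.6,52.7,69.5,93.9
Specificity,89.2,85.9,83.9,78.3,87.1,88.8,87.1,92.7,88.8,98.2,76.8,81.5,100.0
F-measure,75.9,75.8,78.0,74.6,83.5,83.9,83.7,81.5,78.6,92.4,64.2,75.4,98.1
MCC,43.0,53.1,56.6,49.3,67.2,68.2,67.6,58.8,49.5,85.4,30.4,51.4,95.6
AUC,74.5,80.9,81.9,80.1,85.9,85.2,85.9,79.9,73.5,92.9,58.6,80.7,96.9
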