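Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,75.0,77.2,79.1,73.6,84.3,84.4,84.4,81.8,75.0,93.2,64.8,75.8,98.8
Sensitivity,47.3,62.5,71.5,68.4,77.5,78.3,77.9,60.7,47.3,99.1,50.9,67.1,95.9
Specificity,89.2,88.4,85.5,78.3,90.0,89.6,90.0,92.7,89.2,85.7,76.8,83.1,100.0
F-measure,74.9,75.0,78.4,73.3,83.7,83.9,83.9,81.7,74.9,92.4,63.2,74.9,98.8
MCC,40.6,52.7,57.6,47.0,68.0,68.3,68.4,58.1,40.6,85.6,28.7,50.9,97.1
AUC,72.5,79.7,81.4,79.0,85.5,84.5,85.6,80.3,72.5,92.8,57.4,79.6,98.0
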