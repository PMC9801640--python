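Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,73.5,77.9,76.8,74.9,75.0,79.8,77.8,84.6,78.5,86.1,74.8,78.3,93.0
Sensitivity,59.7,82.4,83.6,81.2,71.8,82.0,79.8,83.2,70.9,84.0,75.4,82.6,95.0
Specificity,81.4,73.0,68.8,67.8,78.0,77.4,75.8,85.8,83.1,88.1,74.3,73.5,90.4
F-measure,73.6,77.7,76.1,74.4,74.9,79.7,77.8,84.5,78.5,86.0,74.8,78.0,93.0
MCC,41.7,55.6,53.0,49.4,49.9,59.5,55.6,68.9,54.2,72.1,49.6,56.3,85.7
AUC,75.1,79.6,76.1,78.9,79.0,84.8,80.7,85.4,80.4,86.6,74.2,80.2,93.4
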