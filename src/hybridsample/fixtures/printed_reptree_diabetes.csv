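Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,74.8,77.0,76.5,75.0,75.2,79.1,79.1,84.0,76.0,88.5,73.7,79.4,91.9
Sensitivity,58.2,76.2,83.4,79.6,73.4,78.2,79.6,82.1,63.1,84.0,74.3,81.3,94.3
Specificity,84.6,77.8,68.4,70.0,77.0,80.0,78.6,85.8,84.3,92.5,73.1,77.3,88.6
F-measure,74.9,77.0,75.8,74.7,75.2,79.1,79.1,83.9,76.0,88.2,73.7,79.3,91.8
MCC,44.4,54.0,52.4,49.8,50.4,58.2,58.2,67.8,48.6,76.8,47.4,58.7,83.4
AUC,76.7,81.3,77.8,79.7,79.4,86.1,84.8,90.1,80.1,91.7,76.6,81.5,94.5
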