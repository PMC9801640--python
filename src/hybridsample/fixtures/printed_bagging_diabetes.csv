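Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,74.1,81.0,81.0,79.0,75.6,81.4,79.9,86.4,79.8,87.7,76.7,81.6,95.1
Sensitivity,63.1,86.2,88.2,86.4,78.2,84.8,83.6,86.6,75.4,87.7,78.7,87.0,97.7
Specificity,80.0,75.0,72.2,70.0,72.8,77.6,75.8,86.3,82.0,87.7,74.6,75.4,91.7
F-measure,74.1,80.5,80.1,78.1,75.5,81.2,79.7,86.4,79.6,87.7,76.7,81.1,95.0
MCC,43.0,61.6,61.2,57.2,51.1,62.6,59.6,72.8,56.9,75.4,53.4,62.8,90.0
AUC,78.7,88.3,86.3,86.7,83.4,89.4,87.4,93.4,84.5,94.7,82.9,88.5,98.5
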