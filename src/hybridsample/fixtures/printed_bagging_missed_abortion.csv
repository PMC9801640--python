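Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,75.7,76.0,78.6,72.0,84.6,83.7,84.5,82.1,75.7,91.9,58.1,76.7,97.6
Sensitivity,48.2,66.9,71.9,66.0,78.3,78.3,78.7,61.6,48.2,86.6,53.6,69.9,91.8
Specificity,89.6,83.5,84.3,77.5,90.0,88.4,89.6,92.7,89.6,96.4,62.5,82.7,100.0
F-measure,75.5,75.1,78.0,71.7,84.1,83.3,84.1,81.5,75.5,91.5,58.0,76.2,97.5
MCC,42.1,51.2,56.7,43.8,68.7,67.0,68.7,58.8,42.1,83.4,16.1,53.1,94.2
AUC,73.8,81.7,82.1,79.3,86.9,86.2,87.1,82.5,73.8,93.0,59.5,80.8,98.9
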