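Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,74.8,81.7,82.7,82.1,77.6,81.9,81.5,87.8,79.5,90.4,78.0,84.1,95.1
Sensitivity,61.6,85.8,88.2,87.0,77.6,81.4,82.8,87.7,69.8,87.7,78.0,87.0,97.0
Specificity,82.4,77.2,76.2,76.4,77.6,82.4,80.2,87.9,85.6,92.9,78.0,80.9,92.6
F-measure,75.0,81.5,82.1,81.6,77.6,81.9,81.5,87.8,79.5,90.3,78.0,83.9,95.1
MCC,44.6,63.2,64.9,63.8,55.2,63.8,63.0,75.5,56.2,80.7,56.0,68.0,90.0
AUC,81.9,89.5,89.0,89.2,86.4,90.5,89.7,95.0,85.9,96.2,85.5,91.0,98.9
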