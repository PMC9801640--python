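Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,69.2,75.4,73.3,72.3,72.0,76.7,74.1,81.9,74.5,84.0,71.4,78.8,92.2
Sensitivity,55.6,78.2,72.6,73.0,71.2,78.6,74.6,82.1,68.3,85.4,67.9,77.9,94.6
Specificity,76.6,72.4,74.0,71.6,72.8,74.8,73.6,81.7,77.8,82.5,74.6,79.6,89.1
F-measure,69.2,75.3,73.3,72.3,72.0,76.7,74.1,81.9,74.3,84.0,71.2,78.8,92.2
MCC,32.3,50.7,46.6,44.6,44.0,53.4,48.2,63.7,45.6,67.9,42.6,57.6,84.1
AUC,66.1,75.3,73.3,72.3,72.0,76.7,74.1,81.9,73.0,84.0,71.3,78.8,91.9
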