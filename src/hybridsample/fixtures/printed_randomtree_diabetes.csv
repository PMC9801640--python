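Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,69.1,76.5,74.1,73.1,71.5,77.4,74.6,83.9,73.4,85.1,72.4,78.1,93.2
Sensitivity,55.2,76.6,74.6,76.6,70.8,78.2,74.0,86.2,63.8,86.9,71.3,79.4,95.4
Specificity,76.6,76.4,73.6,69.4,71.8,76.6,75.2,81.3,79.3,83.2,73.5,76.7,90.4
F-measure,69.1,76.5,74.1,73.0,71.3,77.4,74.6,83.8,73.4,85.1,72.4,78.0,93.2
MCC,31.9,53.0,48.2,46.1,42.6,54.8,49.2,67.6,43.3,70.2,44.8,56.1,86.1
AUC,65.9,76.5,74.1,73.0,71.3,77.4,74.6,83.7,71.6,85.1,72.4,78.0,92.8
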