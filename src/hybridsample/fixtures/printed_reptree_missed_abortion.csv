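Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,75.4,74.3,73.0,69.2,81.8,82.1,82.6,78.7,75.4,90.0,58.9,71.0,97.0
Sensitivity,44.6,65.3,66.7,61.1,75.1,75.1,75.9,44.6,44.6,80.4,60.7,64.3,91.8
Specificity,90.8,81.9,78.7,76.3,87.6,88.0,88.4,95.0,90.8,97.3,57.1,77.1,99.1
F-measure,74.8,73.5,72.6,68.6,81.3,81.4,82.1,75.8,74.8,88.8,58.9,70.6,96.9
MCC,40.8,47.9,45.7,37.9,63.1,63.6,64.8,48.4,40.8,78.8,17.9,41.7,92.7
AUC,73.9,74.2,74.4,74.6,85.6,85.2,84.6,77.1,73.9,90.0,59.2,74.6,92.8
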