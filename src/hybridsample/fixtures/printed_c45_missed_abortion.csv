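Metric,Original,SM,BSM,ASM,GSM,KSM,CSM,ENN,TL,IHU,RBU,SMTOM,SMENN
Precision,76.0,71.0,76.0,71.2,84.2,84.7,83.7,81.8,76.0,91.2,58.2,75.2,97.1
Sensitivity,46.4,64.1,70.7,61.9,77.9,79.5,76.7,57.1,46.4,98.2,50.0,64.7,89.8
Specificity,90.8,82.3,80.7,79.1,89.6,89.2,89.6,94.1,90.8,82.1,66.1,83.9,100.0
F-measure,75.5,73.0,75.6,70.3,83.7,84.3,83.1,80.5,75.5,90.1,57.8,74.1,96.9
MCC,42.4,47.2,51.7,41.7,67.9,69.0,66.8,57.3,42.4,81.4,16.3,49.5,92.7
AUC,70.4,74.1,74.8,73.5,86.3,86.5,86.7,77.6,70.4,90.5,59.3,74.6,91.2
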