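segment_code,description,multiplier
lm,Left main coronary artery,5
lad_prox,Left anterior descending - proximal,2.5
lad_mid,Left anterior descending - mid,1.5
lad_dist,Left anterior descending - distal,1
diag1,First diagonal branch,0.5
diag2,Second diagonal branch,0.5
lcx_prox,Left circumflex - proximal,2.5
lcx_dist,Left circumflex - distal,0.5
om,Obtuse marginal branch,1
rca_prox,Right coronary artery - proximal,1
rca_mid,Right coronary artery - mid,1
rca_dist,Right coronary artery - distal,1
pda,Posterior descending artery,1
plb,Posterolateral branch,1
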