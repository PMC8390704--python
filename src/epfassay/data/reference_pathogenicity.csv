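isolate_id,species,instar2_lm_pct,instar2_se,instar3_lm_pct,instar3_se,cadaver_spore_conc,reselected
AAUB03,Beauveria bassiana,94.7,3.08,93.3,2.00,1.6e7,1
AAUB29,Beauveria bassiana,92.0,1.20,95.0,3.05,1.1e7,1
AAUB28,Beauveria bassiana,95.7,2.67,95.0,2.12,2.1e7,1
AAUB76,Beauveria bassiana,88.3,1.09,85.0,3.10,1.5e6,1
AAUB24,Beauveria bassiana,81.7,3.62,84.0,2.36,8.3e6,0
AAUB05,Beauveria bassiana,71.0,2.01,75.3,3.76,4.6e6,0
AAUB59,Beauveria bassiana,85.0,2.50,89.0,2.24,1.2e7,1
AAUB39,Beauveria bassiana,86.7,4.00,83.3,3.98,1.2e7,1
AAUB46,Beauveria bassiana,73.0,2.30,71.7,3.61,7.3e6,0
AAUB19,Beauveria bassiana,94.7,1.08,92.0,4.10,3.5e7,1
AAUB90,Beauveria bassiana,92.0,1.20,90.0,3.02,1.2e7,1
AAUB06,Beauveria bassiana,65.7,2.67,68.3,1.89,5.9e6,0
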