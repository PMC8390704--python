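isolate_id,genus,soil,sg_pct,sg_se,dpcs_day,dpcs_se,rsr,lm_pct,lm_se,bei_pct,bei_se,selected
AAUB76,Beauveria,cropland,94.0,2.60,10.7,2.44,1.876,100,0.00,85.0,1.25,1
AAUB28,Beauveria,cropland,94.0,1.87,11.0,1.60,1.818,100,0.00,85.0,0.75,1
AAUB90,Beauveria,cropland,90.7,3.17,11.2,2.02,1.792,100,0.00,83.8,1.98,1
AAUB19,Beauveria,cropland,93.3,1.43,11.5,0.39,1.739,100,0.00,84.8,1.67,1
AAUB39,Beauveria,cropland,92.0,3.23,12.7,2.32,1.580,100,0.00,84.3,2.12,1
AAUB45,Beauveria,cropland,81.3,4.12,14.0,0.86,1.429,90.0,3.23,75.3,3.41,0
AAUB46,Beauveria,cropland,90.7,2.28,11.3,2.43,1.765,90.0,3.32,78.7,2.87,0
AAUB22,Beauveria,cropland,86.3,2.45,15.0,0.82,1.333,91.3,1.67,77.8,3.21,0
AAUB49,Beauveria,cropland,92.0,4.00,15.0,1.09,1.333,86.7,1.67,77.5,2.45,0
AAUB25,Beauveria,cropland,89.0,2.09,12.2,3.00,1.645,86.7,1.78,76.5,2.06,0
AAUB70,Beauveria,cropland,87.3,3.18,11.2,2.08,1.792,89.0,4.02,77.1,3.56,0
AAUB08,Beauveria,cropland,91.0,2.06,14.8,1.45,1.349,83.3,1.07,75.5,1.12,0
AAUB60,Beauveria,cropland,84.3,1.65,12.7,1.12,1.580,86.7,1.67,74.7,1.89,0
AAUB85,Beauveria,cropland,85.7,4.23,13.0,2.09,1.538,80.0,2.00,71.9,3.80,0
AAUB18,Beauveria,cropland,85.7,2.68,13.0,0.34,1.538,76.7,2.78,70.2,4.56,0
AAUB05,Beauveria,grassland,94.0,2.09,13.6,0.64,1.467,100,0.00,85.0,2.34,1
AAUB03,Beauveria,grassland,96.7,3.06,10.8,1.44,1.847,100,0.00,86.0,1.92,1
AAUB06,Beauveria,grassland,91.3,1.10,14.3,2.00,1.396,100,0.00,84.0,2.34,1
AAUB07,Beauveria,grassland,43.3,3.19,14.0,1.53,1.429,92.2,4.08,62.3,5.03,0
AAUB59,Beauveria,forest,92.3,1.45,11.2,1.15,1.792,100,0.00,84.4,2.57,1
AAUB24,Beauveria,forest,97.0,4.20,12.0,1.10,1.667,100,0.00,86.1,1.56,1
AAUB23,Beauveria,forest,88.3,2.45,14.3,1.27,1.397,100,0.00,82.9,3.67,1
AAUB29,Beauveria,forest,91.7,1.89,12.3,0.72,1.622,96.7,3.67,82.5,2.56,1
AAUB26,Beauveria,forest,91.0,4.29,11.0,2.10,1.818,90.0,2.70,78.9,3.78,0
AAUB69,Beauveria,forest,90.7,2.54,16.0,1.78,1.250,86.7,3.78,77.0,3.86,0
AAUB09,Beauveria,forest,90.7,3.00,15.0,1.60,1.333,86.7,3.67,77.1,5.12,0
AAUB20,Beauveria,forest,94.7,0.89,14.7,2.02,1.364,83.3,3.67,76.9,2.67,0
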