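combination	S1	S2	S3	S4	S5	S6	S7
Mean and Slope	53.82	50.81	50.69	59.22	59.84	55.21	59.84
Mean and Peak	94.61	96.48	90.71	91.96	90.96	91.96	94.85
Mean and Variance	86.57	87.21	81.93	82.93	82.81	75.53	83.43
Slope and Peak	87.07	83.31	80.92	85.44	83.81	83.56	81.18
Slope and Variance	86.95	88.71	83.43	82.81	81.81	76.78	80.55
Peak and Variance	89.71	89.96	83.56	87.71	87.21	83.68	81.31
Peak and Skewness	89.08	83.44	80.55	86.71	81.81	83.06	81.05
Mean and Skewness	48.11	49.56	49.81	53.07	52.94	51.94	50.31
Slope and Skewness	47.43	50.31	47.81	53.58	52.57	54.21	50.06
Kurtosis and Skewness	46.17	48.55	51.56	54.21	48.93	53.58	50.56
Variance and Skewness	87.82	88.58	82.31	83.18	81.55	78.29	84.19
Peak and Kurtosis	86.82	82.43	80.93	85.57	83.93	82.06	81.05
Mean and Kurtosis	46.92	46.67	51.44	53.71	49.05	52.07	48.43
Slope and Kurtosis	47.55	45.29	53.45	54.07	52.19	49.18	48.18
Variance and Kurtosis	87.45	88.33	82.18	83.31	82.31	82.18	85.95
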