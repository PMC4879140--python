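combination	S1	S2	S3	S4	S5	S6	S7
Mean and Slope	56.83	54.45	61.61	59.59	55.33	56.71	62.86
Mean and Peak	92.34	92.59	90.84	91.84	88.71	86.07	87.07
Mean and Variance	82.43	86.82	82.93	85.94	82.55	79.92	79.54
Slope and Peak	86.07	86.32	79.67	85.44	85.19	83.06	84.69
Slope and Variance	79.79	87.32	82.31	85.82	80.55	76.41	77.91
Peak and Variance	85.44	86.07	82.93	87.21	86.32	76.91	84.31
Peak and Skewness	88.33	87.21	84.44	85.94	84.94	80.81	85.44
Mean and Skewness	51.69	51.31	53.32	52.82	47.05	54.71	59.47
Slope and Skewness	52.44	52.07	57.34	51.31	51.94	47.55	54.83
Kurtosis and Skewness	52.94	48.81	55.21	49.43	45.42	56.46	52.69
Variance and Skewness	82.55	81.93	83.81	86.71	80.92	77.03	78.16
Peak and Kurtosis	86.95	83.81	81.43	86.07	85.69	78.67	86.44
Mean and Kurtosis	50.06	54.57	55.33	45.42	48.55	60.47	57.59
Slope and Kurtosis	51.81	49.43	54.21	48.55	49.31	56.21	59.09
Variance and Kurtosis	86.32	85.94	85.44	86.71	82.05	78.16	78.41
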