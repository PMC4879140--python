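combination	S1	S2	S3	S4	S5	S6	S7
Mean, Peak, and Slope	94.47	96.48	90.46	91.96	90.58	92.34	94.35
Mean, Peak, and Kurtosis	95.15	96.36	90.96	92.09	91.96	93.22	94.98
Mean, Peak, and Skewness	94.98	96.61	90.58	93.09	92.34	92.47	94.85
Mean, Peak, and Variance	94.35	96.98	91.21	92.34	91.84	91.84	94.73
Peak, Slope, and Skewness	89.08	84.19	79.79	86.95	85.44	83.93	81.43
Peak, Kurtosis, and Variance	89.83	89.58	84.06	87.07	87.45	84.06	81.92
Peak, Slope, and Variance	90.08	90.21	84.31	87.72	86.71	83.68	80.92
Variance, Slope, and Kurtosis	87.57	89.08	82.68	82.43	82.68	78.92	81.55
Variance, Slope, and Mean	87.82	87.95	83.06	83.56	83.31	77.66	80.31
Variance, Mean, and Skewness	87.71	87.82	82.81	82.93	83.06	75.15	83.93
Variance, Mean, and Kurtosis	87.32	88.08	81.93	82.81	83.56	82.05	84.94
Kurtosis, Peak, and Slope	83.56	83.43	81.05	85.69	84.69	83.18	81.17
Kurtosis, Skewness, and Mean	43.78	50.43	56.33	53.19	48.68	52.94	48.05
Slope, Mean, and Skewness	49.68	48.68	48.93	53.95	55.58	51.69	49.32
Slope, Skewness, and Kurtosis	44.66	50.56	50.94	57.08	51.31	52.94	46.17
Slope, Mean, and Kurtosis	43.53	44.16	53.32	56.71	55.33	52.07	47.45
Slope, Skewness, and Variance	87.57	89.08	83.31	83.43	81.55	75.03	80.05
Skewness, Variance, and Kurtosis	87.95	88.83	82.55	83.18	82.81	84.19	86.57
Skewness, Peak, and Kurtosis	88.71	82.93	81.93	86.57	85.44	83.43	81.55
Skewness, Variance, and Peak	90.21	89.83	84.44	87.82	86.82	83.43	81.31
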