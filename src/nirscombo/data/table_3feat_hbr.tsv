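combination	S1	S2	S3	S4	S5	S6	S7
Mean, Peak, and Slope	93.09	91.59	90.96	92.22	88.2	86.44	87.45
Mean, Peak, and Kurtosis	92.97	93.45	91.46	92.34	89.46	86.19	88.2
Mean, Peak, and Skewness	93.97	94.11	92.09	93.97	91.71	86.57	88.71
Mean, Peak, and Variance	93.47	92.84	90.33	92.09	88.83	88.08	92.09
Peak, Slope, and Skewness	88.95	89.08	84.56	86.07	85.94	83.68	84.18
Peak, Kurtosis, and Variance	87.07	88.08	84.06	88.45	87.07	78.16	84.56
Peak, Slope, and Variance	86.82	88.45	83.6	87.07	85.94	84.06	84.31
Variance, Slope, and Kurtosis	82.31	87.95	85.19	86.32	82.55	76.53	79.29
Variance, Slope, and Mean	79.17	87.45	82.05	85.82	82.81	79.42	79.67
Variance, Mean, and Skewness	82.31	86.82	83.18	86.57	83.18	80.05	78.79
Variance, Mean, and Kurtosis	86.07	87.07	85.19	86.44	83.43	79.92	79.54
Kurtosis, Peak, and Slope	87.57	86.44	81.55	86.32	85.82	83.43	84.94
Kurtosis, Skewness, and Mean	50.69	49.56	54.83	44.54	45.29	59.72	57.71
Slope, Mean, and Skewness	50.81	52.81	56.83	53.19	51.81	51.44	57.21
Slope, Skewness, and Kurtosis	48.18	56.83	52.82	47.81	45.54	56.71	59.84
Slope, Mean, and Kurtosis	49.18	55.45	52.19	45.04	49.05	61.11	58.09
Slope, Skewness, and Variance	80.42	86.71	83.34	86.71	81.31	76.41	77.66
Skewness, Variance, and Kurtosis	86.07	86.19	85.57	87.45	82.18	77.91	78.41
Skewness, Peak, and Kurtosis	89.48	85.14	86.07	84.23	85.08	84.24	85.44
Skewness, Variance, and Peak	88.33	89.58	87.45	89.83	87.95	78.67	82.05
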