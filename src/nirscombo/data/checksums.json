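{
 "table_2feat_hbo.tsv": "86695f741d1421c8e243c08c2088d93475b1411397cf3bdf427714a50af9e1d2",
 "table_2feat_hbr.tsv": "774bb222f668c9e6927e847f40ba287e2dd482ee8c525b69e4cdf583c301e30f",
 "table_3feat_hbo.tsv": "440971d2feec6df9b3980c81a48dab4dcc9358c62b1320d6573dd3c7ad766ce8",
 "table_3feat_hbr.tsv": "5da72ed2258ce0baa157c942f2691e55e244067159121fbb73fc91ef9ca68694"
}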