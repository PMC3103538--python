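# GCN4 leucine zipper pK1/2 benchmark (33-residue fragment, Gly0-Ser1 N-terminal
# dipeptide, Glu32 appended): model-compound pK values, continuum-electrostatics
# calculations based on the crystal structure (xray), on the all-charged MD
# conformer set alone (allc_only), on the weighted multi-regime combination
# (full_md), and NMR-titration experimental values.
site	pk_mod	pk_xray	pk_allc_only	pk_full_md	pk_exp
N-terminal	7.5	7.15	8.31	8.22	7.88
Lys3	10.4	10.73	11.22	10.89	10.78
Glu6	4.4	5.14	3.78	4.59	4.6
Asp7	4.0	4.70	3.89	3.52	3.48
Lys8	10.4	10.82	12.02	11.07	11.26
Glu10	4.4	5.86	5.05	5.14	3.94
Glu11	4.4	3.79	2.19	3.95	4.05
Lys15	10.4	11.70	10.55	10.47	10.62
Tyr17	9.6	10.80	10.09	10.39	9.82
His18	6.4	4.56	5.77	5.79	6.24
Glu20	4.4	4.72	4.08	4.48	4.38
Glu22	4.4	3.17	1.18	4.07	4.2
Lys27	10.4	9.3	11.93	11.03	11.1
Lys28	10.4	11.40	10.55	10.52	10.64
Glu32	4.4	4.02	2.07	4.43	4.62
C-terminal	3.8	4.46	3.725	3.17	4.03
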