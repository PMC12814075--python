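gene	lfc_mid_vs_early	lfc_end_vs_mid	p_mid_vs_early	p_end_vs_mid
Aldoa	0.34	0.29	0.001	0.001
Anp32b	0.27	0.38	0.001	0.001
Aprt	0.27	0.32	0.001	0.001
Arl4a	0.31	0.25	0.001	0.001
Atf5	0.33	0.28	0.001	0.001
Capza2	0.79	2.53	0.001	0.001
Cct5	0.39	0.32	0.001	0.001
Cdkn2a	0.98	0.34	0.001	0.001
Eef1a1	0.48	0.47	0.001	0.001
Eef1b2	0.45	0.27	0.001	0.001
Eif3e	0.27	0.33	0.001	0.001
Eif5a	0.30	0.28	0.001	0.001
Fkbp3	0.28	0.32	0.001	0.001
H2afz	0.58	0.43	0.001	0.001
Igfbp2	0.36	0.40	0.001	0.001
Iigp1	0.71	0.36	0.001	0.001
Lgals1	0.42	0.90	0.001	0.001
Lmo4	0.29	0.27	0.001	0.001
Met	0.92	1.62	0.001	0.001
Mif	0.34	0.33	0.001	0.001
Moxd1	0.29	0.42	0.001	0.001
Noct	0.32	0.37	0.001	0.001
Npm1	0.30	0.46	0.001	0.001
Pebp1	0.35	0.29	0.001	0.001
Phlda1	0.27	0.44	0.001	0.001
Rpl19	0.31	0.26	0.001	0.001
Rpl30	0.40	0.30	0.001	0.001
Rpl37	0.29	0.30	0.001	0.001
Rpl8	0.42	0.44	0.001	0.001
Rps12	0.44	0.33	0.001	0.001
Rps3	0.58	0.26	0.001	0.001
Rps4x	0.57	0.28	0.001	0.001
Rps9	0.44	0.34	0.001	0.001
S100a10	0.52	0.27	0.001	0.001
Timp1	0.31	0.29	0.001	0.001
Tpm1	0.28	0.54	0.001	0.001
Tshz2	0.40	0.36	0.001	0.001
Tubb5	0.44	0.31	0.001	0.001
Ube2c	0.40	0.52	0.001	0.001
Ube2s	0.37	0.31	0.001	0.001
Uchl1	0.34	0.69	0.001	0.001
Vim	0.93	0.29	0.001	0.001
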