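M0346	3
M0070	3
M0118	2
M0206	3
M0034	3
M0033	2
M0235	3
M0051	5
M0312	4
M0069	2
M0050	4
M0123	2
M0248	3
M0202	2
M0007	5
M0171	3
M0255	2
M0336	2
M0117	2
M0006	4
M0131	2
M0212	6
M0017	3
M0326	7
M0218	12
M0078	3
M0314	4
M0324	13
M0175	4
M0348	2
M0045	5
M0003	3
M0147	7
M0121	2
M0269	2
M0253	3
M0026	3
M0188	5
M0130	4
M0159	2
M0213	4
M0249	2
M0055	3
M0272	2
M0122	2
M0060	2
M0148	2
M0303	2
M0029	2
M0071	3
M0099	6
M0126	6
M0262	2
M0177	14
M0013	4
M0021	2
M0015	2
M0228	6
M0058	2
M0211	2
M0309	2
M0154	2
M0244	2
M0209	2
M0270	3
M0063	4
M0328	2
M0039	2
M0252	3
M0036	2
M0080	2
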