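gene	description	fc_high	p_high	fc_low	p_low
numr-1	unknown	140.416	4.44E-09	25.1465	5.73E-08
W06H8.2	unknown	91.5165	2.23E-09	25.2296	1.67E-08
gst-30	glutathione S-transferase	64.4519	2.75E-10	12.8297	5.18E-09
T19D12.3	unknown	63.3912	2.67E-09	16.5752	2.76E-08
ftn-1	ferritin heavy chain	55.3853	2.60E-08	5.7706	3.57E-06
hsp-70	heat shock protein 70	53.7595	8.41E-09	14.8787	8.61E-08
F55G11.2	unknown	46.5611	1.05E-08	23.5514	3.39E-08
gst-38	glutathione S-transferase	44.4153	2.61E-10	25.1488	6.92E-10
F56D5.3	NADH oxidase	42.8716	4.55E-07	9.13127	1.04E-05
clec-3	unknown	42.2267	1.34E-07	10.7623	1.986E-06
hsp-16.41	heat shock protein	37.3042	5.15E-09	21.7315	1.36E-08
gst-12	glutathione S-transferase	32.4796	2.51E-08	13.1085	1.52E-07
hsp-16.2	heat shock protein	31.7514	6.75E-08	15.6115	2.66E-07
gst-25	glutathione S-transferase	29.8987	2.85E-09	6.60598	9.57E-08
dod-17	unknown	27.2977	1.12E-08	9.87008	1.01E-07
Y38E10A.13	unknown	26.7901	2.41E-06	4.21829	0.0002776
clec-163	C-type lectin	26.6706	3.41E-09	6.12515	1.19E-07
aip-1	AN-1-like zinc finger-containing protein	20.8251	1.36E-08	4.29368	1.08E-06
F44E5.4	Hsp70 family	18.5558	2.86E-09	6.50486	4.08E-08
clec-2	C-type lectin	17.5573	1.56E-08	5.14494	4.39E-07
gst-16	glutathione S-transferase	16.8344	3.30E-09	8.24937	1.89E-08
F43E2.5	methionine sulfoxide-S-reductase (MsrA)	16.6723	5.69E-09	5.49549	1.14E-07
hsp-16.1	heat shock protein HSP16-1	14.9708	1.10E-07	6.90193	8.15E-07
sdz-8	alcohol dehydrogenase	14.765	1.73E-10	6.55788	1.49E-09
ZK742.4	predicted NADH:flavin oxidoreductase	14.2453	9.39E-09	7.42734	5.04E-08
H20E11.2	unknown	14.2209	6.13E-09	7.25052	3.53E-08
gst-5	glutathione S-transferase	12.8611	3.93E-10	6.47925	2.56E-09
C32H11.4	unknown	12.2617	1.28E-11	9.75833	2.26E-11
Y52E8A.3	unknown	11.9775	1.94E-09	10.165	2.92E-09
hsp-16.48	heat shock protein	11.9585	8.18E-09	7.00906	3.49E-08
F49F1.6	containing a signal sequence and ShK toxin domains	10.8365	1.28E-08	4.10812	2.90E-07
cdr-4	glutathione S-transferase	10.6628	1.14E-08	4.46537	1.76E-07
Y40B10A.2	unknown	9.86761	5.76E-10	4.30897	8.49E-09
C55A6.6	alcohol dehydrogenase	9.78048	5.79E-08	5.28538	3.77E-07
ugt-13	ugt family	9.63811	1.88E-06	7.71078	3.47E-06
clec-143	C-type lectin	9.15882	1.75E-08	4.8121	1.36E-07
nit-1	Nitrilase	7.82259	7.22E-08	4.76861	3.72E-07
gst-4	glutathione S-transferase	7.60112	9.16E-09	5.85187	2.09E-08
C17H12.6	unknown	6.8668	1.65E-07	6.55322	1.91E-07
clec-9	C-type lectin	6.4249	1.88E-06	6.405	1.90E-06
dod-24	unknown	5.66907	6.82E-09	4.92816	1.13E-08
gst-7	glutathione S-transferase	4.92498	7.38E-08	4.22807	1.34E-07
C32H11.3	unknown	4.57737	3.54E-07	4.55978	3.60E-07
C12C8.2	cystathionine gamma-lyase orthologous to human CTH	4.22098	2.29E-07	4.30506	2.11E-07
gst-20	glutathione S-transferase	4.16523	3.23E-07	4.9671	1.61E-07
F55G1.9	carboxylate reductase	4.09065	4.49E-09	4.61329	2.75E-09
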