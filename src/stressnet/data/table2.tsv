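gene_class	gene	p	fold
Glutathione S-Transferase	gst-1	7.05368E-08	3.67142
Glutathione S-Transferase	gst-2	1.23816E-06	16.4022
Glutathione S-Transferase	gst-3	0.000598368	2.02115
Glutathione S-Transferase	gst-4	9.15939E-09	7.60112
Glutathione S-Transferase	gst-5	3.92978E-10	12.8611
Glutathione S-Transferase	gst-6	6.35087E-08	3.62039
Glutathione S-Transferase	gst-7	7.37605E-08	4.92498
Glutathione S-Transferase	gst-8	0.000617048	2.08152
Glutathione S-Transferase	gst-9	1.05337E-06	10.5567
Glutathione S-Transferase	gst-10	1.08689E-05	1.58882
Glutathione S-Transferase	gst-12	2.51366E-08	32.4796
Glutathione S-Transferase	gst-13	2.19643E-08	7.52696
Glutathione S-Transferase	gst-14	3.17455E-06	5.83786
Glutathione S-Transferase	gst-16	3.30181E-09	16.8344
Glutathione S-Transferase	gst-19	4.29809E-08	-8.44166
Glutathione S-Transferase	gst-20	3.22626E-07	4.16523
Glutathione S-Transferase	gst-22	2.83887E-05	1.85819
Glutathione S-Transferase	gst-23	0.00140456	-1.38266
Glutathione S-Transferase	gst-25	2.85006E-09	29.8987
Glutathione S-Transferase	gst-26	1.01402E-08	-7.46037
Glutathione S-Transferase	gst-27	6.8661E-11	-3.00299
Glutathione S-Transferase	gst-28	4.10692E-06	-3.23139
Glutathione S-Transferase	gst-29	0.00104296	-1.92675
Glutathione S-Transferase	gst-30	2.74896E-10	64.4519
Glutathione S-Transferase	gst-31	6.48964E-07	9.26347
Glutathione S-Transferase	gst-36	0.00580448	1.21481
Glutathione S-Transferase	gst-38	2.6131E-10	44.4153
Glutathione S-Transferase	gst-39	1.262E-08	3.78938
Glutathione S-Transferase	gst-40	4.63406E-09	9.47291
Glutathione S-Transferase	gst-42	1.24648E-07	-2.85235
Glutathione S-Transferase	gstk-1	0.000165975	-1.60882
Glutathione S-Transferase	gsto-2	2.68578E-06	4.99268
Glutathione S-Transferase	gsto-3	1.13627E-07	5.62192
Superoxide dismutase	sod-1	0.000634797	1.35592
Superoxide dismutase	sod-2	0.00234654	-1.27465
Superoxide dismutase	sod-4	0.000138537	2.49845
Glutathione diSulfide Reductase	C46F11.2	4.28943E-09	3.27018
Flavin-containing MonoOxygenase	fmo-1	0.000092521	1.52425
Flavin-containing MonoOxygenase	fmo-2	9.40436E-07	3.03595
Flavin-containing MonoOxygenase	fmo-3	0.000199546	-1.34887
Flavin-containing MonoOxygenase	fmo-5	5.92737E-05	-1.60891
Glutamate Synthase	W07E11.1	0.00131395	-1.54529
Catalase	ctl-1/ctl-3	1.96717E-06	2.33936
Catalase	ctl-2	3.94594E-07	-1.81633
Glutathione Peroxidase	C11E4.1	9.01179E-05	-2.21564
Glutathione Peroxidase	F26E4.12	0.000013568	2.04773
Glutathione Peroxidase	R05H10.5	9.17508E-06	4.41822
Glutathione Peroxidase	R03G5.5	4.31118E-05	-1.34898
Heat Shock Protein	hsp-1	5.78737E-05	1.52653
Heat Shock Protein	hsp-12.1	2.25089E-05	-2.3433
Heat Shock Protein	hsp-12.2	0.00731473	-1.24178
Heat Shock Protein	hsp-16.1/hsp-16.11	1.09759E-07	14.9708
Heat Shock Protein	hsp-16.2	6.75136E-08	31.7514
Heat Shock Protein	hsp-16.41	5.15451E-09	37.3042
Heat Shock Protein	hsp-16.48/hsp-16.49	8.17801E-09	11.9585
Heat Shock Protein	hsp-17	1.89686E-05	2.13635
Heat Shock Protein	hsp-25	0.0102672	-1.22664
Heat Shock Protein	hsp-3	0.00126013	-1.48891
Heat Shock Protein	hsp-4	0.000494313	1.39174
Heat Shock Protein	hsp-43	8.36411E-06	2.87926
Heat Shock Protein	hsp-6	7.8582E-07	4.9375
Heat Shock Protein	hsp-70	8.41166E-09	53.7595
Heat Shock Protein	F44E5.4	2.85528E-09	18.5558
Hedgehog-like Proteins	grl-10	2.49496E-05	-1.94499
Hedgehog-like Proteins	grl-14	2.3101E-07	2.2902
Hedgehog-like Proteins	grl-4	0.00135253	1.45752
Hedgehog-like Proteins	grl-7	2.50635E-05	-1.86634
Hedgehog-like Proteins	wrt-6	2.49E-03	-1.33577
Hedgehog-like Proteins	wrt-1	1.43E-04	-1.38953
Hedgehog-like Proteins	grd-12	1.18E-02	-1.41453
Hedgehog-like Proteins	wrt-8	8.54E-03	-1.46887
Hedgehog-like Proteins	grd-11	4.22E-03	-1.4916
Hedgehog-like Proteins	grd-2	1.09E-03	-1.56007
Hedgehog-like Proteins	grd-5	9.18E-06	-1.58758
Hedgehog-like Proteins	qua-1	6.25E-04	-1.49428
Hedgehog-like Proteins	hog-1	3.75E-05	-1.61787
Hedgehog-like Proteins	wrt-3	6.93E-04	-1.84712
Hedgehog-like Proteins	wrt-4	6.27E-07	-1.95916
Hedgehog-like Proteins	wrt-2	5.30E-05	-2.25742
Hedgehog-like Proteins	grd-10	3.99E-05	-2.55
Hedgehog-like Proteins	grd-3	1.51E-05	-2.9124
Hedgehog-like Proteins	grd-1	4.69E-05	-3.13208
Hedgehog-like Proteins	wrt-10	3.56E-08	-4.24045
Transcription Factor	skn-1	0.000524389	2.10743
NADH Oxidase	F56D5.3	4.55012E-07	42.8716
Mitochondrial Iron Transporter Sideroflexin	sfxn-2	4.77799E-05	-2.22696
Mitochondrial Iron Transporter Sideroflexin	sfxn-2	0.000478497	-2.32737
Mitochondrial Iron Transporter Sideroflexin	sfxn-5	8.57816E-06	-1.976
Ferritin	ftn-1	2.59928E-08	55.3853
Ferritin	ftn-2	5.85469E-06	2.36642
Ferroportin	fpn-1.1	7.19801E-09	6.49655
Ferroportin	fpn-1.2	7.73361E-06	-2.11996
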