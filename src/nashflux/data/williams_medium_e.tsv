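# medium	WME	percell_volume	0.1111111111111111
species	mass_conc_g_L	mw_g_mol	amount_nmol_cell	molarity_mM	as_printed
glucose	2.0	180.06	1.234	11.074	1
glutamine	0.292	146.07	0.2221	1.999	0
glutathione	5e-05	307.08	2.22e-05	0.00247	1
L-serine	0.01	105.04	0.1057	0.952	1
glycine	0.05	75.03	0.074	0.6664	0
L-alanine	0.09	89.09	0.1122	1.0102	0
L-arginine	0.05	174.11	0.0319	0.2872	0
L-aspartate	0.03	133.04	0.025	0.2254	1
L-cysteine	0.04	121.02	0.0367	0.3306	1
bicarbonate	2.0	60.99	3.6432	32.6943	1
water			6166.666666666666		0
oxygen			0.05555555555555555	0.5	0
co2			0.044444444444444446	0.4	0
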