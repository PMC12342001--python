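# medium	UW	percell_volume	0.0001
species	mass_conc_g_L	mw_g_mol	amount_nmol_cell	molarity_mM	as_printed
glutathione			0.0003	3.0	0
adenosine			0.0005	5.0	0
water			5.54		0
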