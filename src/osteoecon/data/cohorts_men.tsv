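age	total	general_pct	osteoporosis_pct	prevalent_fx_pct
50	85138	0.972	0.026	0.002
60	69040	0.919	0.067	0.014
70	47455	0.885	0.085	0.030
80	29235	0.570	0.360	0.070
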