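age	total	general_pct	osteoporosis_pct	prevalent_fx_pct
50	83691	0.933	0.066	0.001
60	70979	0.819	0.163	0.018
70	52754	0.670	0.286	0.044
80	41157	0.401	0.472	0.127
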