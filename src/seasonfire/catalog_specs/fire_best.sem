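# Best-by-BCC wildfire model: the second-best structure plus direct negative
# nino -> area and tc_wet -> area paths and a weakened rain_dry -> area path.
# No coefficients for this model are published in the text; all values are
# simulation placeholders shaped by the qualitative description.
vars nino tc_wet rain_dry n_fires area
role fitted-best
nino -> rain_dry fixed=0.59 placeholder
tc_wet -> rain_dry fixed=0.35 placeholder
rain_dry -> area fixed=-0.40 placeholder
n_fires -> area fixed=0.51 placeholder
tc_wet -> n_fires fixed=-0.52 placeholder
nino -> area fixed=-0.20 placeholder
tc_wet -> area fixed=-0.20 placeholder
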