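# Best wet-season exploratory model.  The nino -> duration (positive,
# significant) and nino -> tc (strong negative) coefficients appear only in
# the figure; 0.30 and -0.45 are simulation placeholders.
vars nino onset duration rainfall tc
role fitted-best
onset -> duration fixed=-0.72
nino -> duration fixed=0.30 placeholder
duration -> rainfall fixed=0.82
rainfall -> tc fixed=0.75
duration -> tc fixed=-0.60
nino -> tc fixed=-0.45 placeholder
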