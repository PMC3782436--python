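# Best dry-season exploratory model with its published standardized
# coefficients.  The nino -> tc coefficient appears only in the figure
# ("significant but fairly weak" direct negative effect); -0.25 is a
# simulation placeholder, not a published value.
vars nino onset duration rainfall tc
role fitted-best
onset -> duration fixed=-0.69
duration -> rainfall fixed=0.46
nino -> rainfall fixed=0.62
rainfall -> tc fixed=-0.76
duration -> tc fixed=0.53
nino -> tc fixed=-0.25 placeholder
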