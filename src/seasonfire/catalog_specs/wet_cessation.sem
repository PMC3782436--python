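# Wet-season cessation-date variant.  Published: cessation -> duration 0.76,
# duration -> rainfall 0.82, and nino -> cessation 0.35 (ENSO lengthens the
# wet season by delaying its end).  Others mirror the best onset model as
# placeholders.
vars nino cessation duration rainfall tc
role fitted-best
nino -> cessation fixed=0.35
cessation -> duration fixed=0.76
duration -> rainfall fixed=0.82
rainfall -> tc fixed=0.75 placeholder
duration -> tc fixed=-0.60 placeholder
nino -> tc fixed=-0.45 placeholder
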