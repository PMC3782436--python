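# Dry-season cessation-date variant: cessation replaces onset.  Published:
# cessation -> duration 0.53 and duration -> rainfall 0.46 (their product is
# the published indirect effect on rainfall).  Remaining coefficients mirror
# the best onset model as placeholders.
vars nino cessation duration rainfall tc
role fitted-best
cessation -> duration fixed=0.53
duration -> rainfall fixed=0.46
nino -> rainfall fixed=0.62 placeholder
rainfall -> tc fixed=-0.76 placeholder
duration -> tc fixed=0.53 placeholder
nino -> tc fixed=-0.25 placeholder
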