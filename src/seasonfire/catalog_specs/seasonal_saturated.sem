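# Saturated seasonal framework for specification search: every forward-ordered
# path among nino -> onset -> duration -> rainfall -> tc.  The forward ordering
# (no reversed arrows, ENSO upstream of everything) is an encoding assumption;
# with all 10 edges present the model has 0 df.
vars nino onset duration rainfall tc
role saturated-framework
nino -> onset free optional
nino -> duration free optional
nino -> rainfall free optional
nino -> tc free optional
onset -> duration free optional
onset -> rainfall free optional
onset -> tc free optional
duration -> rainfall free optional
duration -> tc free optional
rainfall -> tc free optional
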