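# Wet-season starting model: as dry, plus a direct negative ENSO path to
# trend consistency (El Nino wet-season droughts are not routed via rainfall).
vars nino onset duration rainfall tc
role starting
onset -> duration free
duration -> rainfall free
nino -> rainfall free
rainfall -> tc free
nino -> tc free
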