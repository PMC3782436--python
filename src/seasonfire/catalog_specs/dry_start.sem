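# Dry-season starting model: theory-only edges.
# ENSO raises dry-season rainfall; later onset shortens the season; longer
# seasons collect more rain; rain interrupts the drying trend.
vars nino onset duration rainfall tc
role starting
onset -> duration free
duration -> rainfall free
nino -> rainfall free
rainfall -> tc free
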