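# Wildfire starting model (30 fire years): ENSO raises dry-season rainfall;
# rainfall suppresses fire number and area; fire number raises area; a
# consistent previous wet season suppresses both fire variables.
vars nino tc_wet rain_dry n_fires area
role starting
nino -> rain_dry free
rain_dry -> n_fires free
rain_dry -> area free
n_fires -> area free
tc_wet -> n_fires free
tc_wet -> area free
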