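# Saturated wildfire framework: the starting edges plus every remaining
# forward-ordered path, including nino -> tc_wet (needed to reach 0 df with
# the exogenous covariance fixed at zero; an encoding assumption).
vars nino tc_wet rain_dry n_fires area
role saturated-framework
nino -> tc_wet free optional
nino -> rain_dry free optional
nino -> n_fires free optional
nino -> area free optional
tc_wet -> rain_dry free optional
tc_wet -> n_fires free optional
tc_wet -> area free optional
rain_dry -> n_fires free optional
rain_dry -> area free optional
n_fires -> area free optional
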