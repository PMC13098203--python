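name	stoichiometry
atp	atp_c:-1;h2o_c:-1;adp_c:1;pi_c:1;h_c:1
gtp	gtp_c:-1;h2o_c:-1;gdp_c:1;pi_c:1;h_c:1
nadh	nadh_c:-1;nad_c:1;h_c:1
nadph	nadph_c:-1;nadp_c:1;h_c:1
fadh2	fadh2_c:-1;fad_c:1;h_c:2
proton_gradient	h_e:-1;h_c:1
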