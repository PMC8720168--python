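site	organism
blood	coagulase-negative staphylococcus
blood	viridans group streptococcus
respiratory	candida albicans
respiratory	viridans group streptococcus
urine	mixed flora
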