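category,value_billion_yen,ci_low,ci_high,multiplier,multiplier_ci_low,multiplier_ci_high
economic_impact,72107.4,71018.2,75300.0,2.78,2.74,2.90
primary_impact,44422.7,43214.5,45799.9,1.71,1.67,1.77
direct_effect,25948.4,,,1.00,,
indirect_effect,18474.3,17266.1,19851.5,0.71,0.67,0.77
secondary_impact,27684.7,27237.4,30096.2,1.07,1.05,1.16
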