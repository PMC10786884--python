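class,area_ha
cutaway,54302
cutover,64699
grassland,244100
forestry,116427
remnant_peatland,73795
water,1542
built_up,1358
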