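class,cutaway,cutover,water,forestry,grassland,remnant_peatland,built_up
cutaway,164,12,1,8,2,10,0
cutover,0,91,0,4,15,19,1
water,1,0,35,8,2,0,4
forestry,1,2,0,244,4,1,0
grassland,2,1,1,12,624,6,14
remnant_peatland,1,2,0,2,5,111,0
built_up,0,0,0,3,13,0,34
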