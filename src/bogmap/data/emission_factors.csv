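class,tier,ef_mean,ef_low,ef_high,n_sites,source
cutover,T1,2.8,1.1,4.2,,IPCC Wetlands Supplement (2013) default
cutaway,T1,2.8,1.1,4.2,,IPCC Wetlands Supplement (2013) default
forestry,T1,2.6,2.0,3.3,,IPCC Wetlands Supplement (2013) default
grassland,T1,5.3,3.7,6.9,,IPCC Wetlands Supplement (2013) default
cutover,T2,1.21,0.4,2.0,3,Irish site-scale flux synthesis
cutaway,T2,1.59,1.2,2.0,4,Irish site-scale flux synthesis
forestry,T2,1.68,1.04,2.32,8,drained afforested peatland sites (Ireland/UK)
grassland,T2,1.3,0.04,2.55,3,Irish site-scale flux synthesis
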