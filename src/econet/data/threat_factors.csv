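threat,source_class,d_max_km,weight,decay
farmland,farmland,4,0.5,linear
construction,construction,10,1,exponential
bare_land,unused,2,3,linear
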