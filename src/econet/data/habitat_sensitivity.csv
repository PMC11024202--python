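class,suitability,farmland,construction,bare_land
farmland,0.2,0.3,0.7,0.5
forest,1,0.7,0.9,0.6
grassland,0.7,0.6,0.6,0.4
water,0.9,0.65,0.85,0.5
construction,0,0,0,0
unused,0,0,0,0
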