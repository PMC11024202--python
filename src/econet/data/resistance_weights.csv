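factor,weight
habitat_quality,0.18
landuse,0.35
ndvi,0.20
elevation,0.09
slope,0.08
relief,0.08
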