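year,sources,source_area_km2,important_sources,important_source_area_km2,general_sources,general_source_area_km2,corridors,corridor_length_km,important_corridors,important_corridor_length_km,general_corridors,general_corridor_length_km
1985,19,209.42,8,159.42,11,50.01,47,745.12,18,164.27,29,580.85
1990,22,219.91,8,161.29,14,58.62,55,745.59,21,175.71,34,569.88
2000,21,216.49,8,160.29,13,56.20,51,720.35,20,173.52,31,546.83
2010,18,193.14,7,152.96,11,40.18,42,555.04,17,140.11,25,414.93
2020,20,201.36,8,156.46,12,44.90,49,624.89,18,146.73,31,478.16
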