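year,class,area_km2,ratio_pct
1985,farmland,2127.08,71.22
1985,forest,282.63,9.46
1985,grassland,42.99,1.44
1985,water,90.49,3.03
1985,construction,439.96,14.73
1985,unused,3.45,0.12
1990,farmland,2116.81,70.88
1990,forest,282.80,9.47
1990,grassland,43.17,1.45
1990,water,98.68,3.30
1990,construction,441.69,14.79
1990,unused,3.45,0.12
2000,farmland,2054.97,68.81
2000,forest,279.31,9.35
2000,grassland,42.34,1.42
2000,water,109.08,3.65
2000,construction,497.45,16.66
2000,unused,3.46,0.12
2010,farmland,1920.90,64.32
2010,forest,261.04,8.74
2010,grassland,26.94,0.90
2010,water,98.27,3.29
2010,construction,675.45,22.62
2010,unused,4.02,0.13
2020,farmland,1850.64,61.97
2020,forest,258.87,8.67
2020,grassland,30.08,1.01
2020,water,99.25,3.32
2020,construction,743.76,25.90
2020,unused,4.04,0.14
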