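year,alpha,beta,gamma
1985,0.88,2.47,0.922
1990,0.87,2.50,0.917
2000,0.85,2.43,0.895
2010,0.81,2.33,0.875
2020,0.86,2.45,0.907
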