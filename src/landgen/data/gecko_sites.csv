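population,elevation_m,n,n_msat,h_obs,h_exp,n_alleles,allelic_richness
Road to Navojoa,455,10,10.0,0.717,0.755,65,65.0
Alamos,375,36,35.2,0.762,0.773,88,64.887
Tabelo A,167,27,26.3,0.701,0.714,70,56.555
Tabelo B,199,30,29.0,0.721,0.734,69,54.234
Aduana,497,17,16.5,0.756,0.78,75,65.606
Rio Cuchujaqui A,358,30,28.9,0.749,0.762,86,65.451
Rio Cuchujaqui B,261,42,41.3,0.772,0.781,83,64.53
Sierrita,483,38,36.4,0.698,0.707,89,63.881
Mocuzari,124,30,29.6,0.701,0.713,70,55.22
El Quintero,361,30,29.0,0.69,0.703,83,61.761
Choquincahui,433,31,29.2,0.709,0.721,81,59.34
San Antonio,388,15,13.6,0.724,0.752,69,62.731
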