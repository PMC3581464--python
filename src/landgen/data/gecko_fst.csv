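,Road to Navojoa,Alamos,Tabelo A,Tabelo B,Aduana,Rio Cuchujaqui A,Rio Cuchujaqui B,Sierrita,Mocuzari,El Quintero,Choquincahui,San Antonio
Road to Navojoa,0.000,0.032,0.080,0.065,-0.003,0.039,0.033,0.042,0.045,0.149,0.140,0.040
Alamos,0.032,0.000,0.080,0.059,0.021,0.028,0.029,0.056,0.063,0.118,0.122,0.019
Tabelo A,0.080,0.080,0.000,0.026,0.058,0.082,0.087,0.154,0.068,0.147,0.142,0.099
Tabelo B,0.065,0.059,0.026,0.000,0.059,0.076,0.075,0.123,0.049,0.151,0.150,0.078
Aduana,-0.003,0.021,0.058,0.059,0.000,0.024,0.031,0.047,0.056,0.128,0.125,0.027
Rio Cuchujaqui A,0.039,0.028,0.082,0.076,0.024,0.000,0.021,0.078,0.055,0.096,0.092,0.040
Rio Cuchujaqui B,0.033,0.029,0.087,0.075,0.031,0.021,0.000,0.069,0.070,0.111,0.114,0.042
Sierrita,0.042,0.056,0.154,0.123,0.047,0.078,0.069,0.000,0.097,0.201,0.199,0.069
Mocuzari,0.045,0.063,0.068,0.049,0.056,0.055,0.070,0.097,0.000,0.150,0.142,0.083
El Quintero,0.149,0.118,0.147,0.151,0.128,0.096,0.111,0.201,0.150,0.000,0.008,0.135
Choquincahui,0.140,0.122,0.142,0.150,0.125,0.092,0.114,0.199,0.142,0.008,0.000,0.144
San Antonio,0.040,0.019,0.099,0.078,0.027,0.040,0.042,0.069,0.083,0.135,0.144,0.000
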