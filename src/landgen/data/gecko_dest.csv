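,Road to Navojoa,Alamos,Tabelo A,Tabelo B,Aduana,Rio Cuchujaqui A,Rio Cuchujaqui B,Sierrita,Mocuzari,El Quintero,Choquincahui,San Antonio
Road to Navojoa,0.000,0.106,0.181,0.174,0.000,0.119,0.075,0.048,0.094,0.325,0.311,0.113
Alamos,0.106,0.000,0.197,0.166,0.072,0.086,0.095,0.139,0.151,0.217,0.309,0.032
Tabelo A,0.181,0.197,0.000,0.050,0.125,0.196,0.223,0.257,0.133,0.260,0.309,0.248
Tabelo B,0.174,0.166,0.050,0.000,0.143,0.224,0.232,0.252,0.100,0.293,0.377,0.197
Aduana,0.000,0.072,0.125,0.143,0.000,0.074,0.084,0.069,0.123,0.207,0.269,0.083
Rio Cuchujaqui A,0.119,0.086,0.196,0.224,0.074,0.000,0.059,0.131,0.150,0.170,0.195,0.134
Rio Cuchujaqui B,0.075,0.095,0.223,0.232,0.084,0.059,0.000,0.137,0.197,0.236,0.319,0.101
Sierrita,0.048,0.139,0.257,0.252,0.069,0.131,0.137,0.000,0.176,0.345,0.378,0.155
Mocuzari,0.094,0.151,0.133,0.100,0.123,0.150,0.197,0.176,0.000,0.267,0.318,0.172
El Quintero,0.325,0.217,0.260,0.293,0.207,0.170,0.236,0.345,0.267,0.000,0.009,0.217
Choquincahui,0.311,0.309,0.309,0.377,0.269,0.195,0.319,0.378,0.318,0.009,0.000,0.336
San Antonio,0.113,0.032,0.248,0.197,0.083,0.134,0.101,0.155,0.172,0.217,0.336,0.000
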