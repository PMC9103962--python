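sector,1997,1998,1999,2000,2001,2002,2003,2004,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014,2015,2016,2017,2018,2019,2020
wine,0.321,0.346,0.359,0.341,0.413,0.496,0.329,0.378,0.267,0.191,0.239,0.330,0.274,0.277,0.335,0.324,0.305,0.204,0.218,0.217,0.254,0.221,0.264,0.189
milk and dairy products,0.081,0.058,0.084,0.068,0.087,0.114,0.122,0.090,0.065,0.086,0.084,0.123,0.160,0.165,0.148,0.157,0.137,0.120,0.168,0.105,0.072,0.039,0.078,0.051
oils and fats,0.086,0.073,0.091,0.128,0.083,0.084,0.090,0.192,0.085,0.072,0.089,0.084,0.130,0.094,0.128,0.123,0.121,0.082,0.084,0.112,0.089,0.054,0.152,0.077
feed and supplements,0.391,0.499,0.594,0.322,0.121,0.061,0.069,0.044,0.054,0.045,0.054,0.066,0.121,0.148,0.198,0.235,0.284,0.231,0.262,0.191,0.162,0.204,0.179,0.106
eggs,0.138,0.166,0.197,0.084,0.137,0.131,0.115,0.189,0.143,0.116,0.079,0.106,0.095,0.207,0.323,0.240,0.163,0.169,0.207,0.17,0.112,0.119,0.101,0.115
honey,0.233,0.188,0.126,0.233,0.171,0.123,0.038,0.093,0.094,0.065,0.058,0.121,0.117,0.078,0.149,0.099,0.124,0.118,0.132,0.103,0.087,0.106,0.1,0.046
sowing seeds,0.585,0.461,0.481,0.502,0.243,0.271,0.238,0.347,0.134,0.109,0.098,0.139,0.431,0.275,0.255,0.068,0.066,0.186,0.167,0.168,0.123,0.122,0.207,0.068
vegetable preserves,0.071,0.055,0.031,0.061,0.142,0.050,0.050,0.059,0.044,0.039,0.071,0.135,0.093,0.136,0.114,0.152,0.135,0.084,0.089,0.104,0.076,0.056,0.041,0.038
meat,0.037,0.024,0.015,0.010,0.002,0.028,0.152,0.112,0.055,0.052,0.059,0.113,0.196,0.268,0.296,0.361,0.300,0.181,0.174,0.234,0.105,0.194,0.134,0.116
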