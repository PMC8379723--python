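pair,observed_male,observed_female,observed_partner,observed_attendance,expected_male,expected_female,expected_partner,expected_attendance,difference_male,difference_female,difference_partner,difference_attendance,p_male,p_female,p_partner,p_attendance
1,0.655,0.673,0.664,0.843,0.531,0.477,0.504,0.740,0.125,0.196,0.160,0.103,0.01,<0.001,<0.001,<0.001
2,0.873,0.889,0.881,0.962,0.476,0.385,0.438,0.811,0.397,0.503,0.442,0.151,<0.001,<0.001,<0.001,<0.001
3,0.840,0.667,0.750,0.879,0.313,0.652,0.502,0.777,0.527,0.015,0.248,0.101,<0.001,0.47,<0.001,<0.001
4,0.882,0.875,0.878,0.948,0.577,0.447,0.500,0.715,0.306,0.428,0.378,0.233,<0.001,<0.001,<0.001,<0.001
5,0.736,0.808,0.779,0.914,0.617,0.388,0.497,0.753,0.119,0.419,0.282,0.161,0.01,<0.001,<0.001,<0.001
6,0.955,0.967,0.963,0.988,0.519,0.259,0.357,0.862,0.436,0.708,0.606,0.126,<0.001,<0.001,<0.001,<0.001
7,0.926,0.905,0.914,0.972,0.429,0.457,0.445,0.800,0.497,0.448,0.469,0.172,<0.001,<0.001,<0.001,<0.001
8,0.526,0.667,0.595,0.818,0.582,0.469,0.528,0.717,-0.055,0.198,0.066,0.101,0.86,<0.001,0.03,<0.001
9,0.864,0.949,0.904,0.954,0.426,0.361,0.394,0.841,0.437,0.587,0.509,0.114,<0.001,<0.001,<0.001,<0.001
10,0.842,1.000,0.912,0.989,0.512,0.295,0.387,0.832,0.330,0.705,0.524,0.157,<0.001,<0.001,<0.001,<0.001
11,0.970,0.929,0.951,0.996,0.335,0.309,0.322,0.893,0.635,0.620,0.628,0.103,<0.001,<0.001,<0.001,<0.001
12,0.800,0.789,0.793,0.983,0.37,0.296,0.323,0.889,0.43,0.493,0.470,0.094,<0.001,<0.001,<0.001,<0.001
13,0.413,0.607,0.473,0.69,0.694,0.578,0.66,0.573,-0.282,0.029,-0.187,0.117,1,0.36,1,<0.001
14,0.861,0.809,0.832,0.985,0.31,0.342,0.327,0.892,0.55,0.467,0.505,0.093,<0.001,<0.001,<0.001,<0.001
15,0.805,0.903,0.846,0.977,0.466,0.387,0.431,0.816,0.339,0.516,0.415,0.162,<0.001,<0.001,<0.001,<0.001
16,0.943,0.952,0.948,0.979,0.409,0.415,0.412,0.822,0.534,0.537,0.536,0.157,<0.001,<0.001,<0.001,<0.001
17,0.905,0.942,0.922,0.969,0.404,0.487,0.443,0.797,0.501,0.455,0.479,0.171,<0.001,<0.001,<0.001,<0.001
18,0.847,0.772,0.801,0.937,0.407,0.359,0.378,0.852,0.441,0.412,0.423,0.084,<0.001,<0.001,<0.001,<0.001
19,0.846,0.722,0.774,0.907,0.478,0.528,0.508,0.739,0.368,0.194,0.266,0.168,<0.001,<0.001,<0.001,<0.001
20,0.535,0.635,0.582,0.833,0.561,0.482,0.526,0.722,-0.026,0.153,0.056,0.111,0.7,<0.001,0.02,<0.001
21,0.974,0.906,0.934,0.999,0.319,0.359,0.342,0.883,0.654,0.547,0.592,0.116,<0.001,<0.001,<0.001,<0.001
22,0.827,0.980,0.903,0.966,0.523,0.408,0.474,0.777,0.304,0.572,0.429,0.189,<0.001,<0.001,<0.001,<0.001
23,0.800,0.673,0.752,0.872,0.443,0.548,0.485,0.748,0.357,0.125,0.267,0.124,<0.001,0.02,<0.001,<0.001
24,0.944,1.000,0.973,0.987,0.559,0.340,0.443,0.804,0.386,0.660,0.529,0.183,<0.001,<0.001,<0.001,<0.001
25,0.812,0.853,0.84,0.914,0.587,0.264,0.374,0.832,0.226,0.589,0.466,0.082,0.03,<0.001,<0.001,<0.001
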