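z_cm,0.0,0.25,0.5,0.75,1.0,1.5,2.0,3.0,4.0,5.0,6.0,7.0,8.0,10.0
-10.0,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.028,0.027,0.024,0.022,0.02,0.018,0.014
-8.0,0.051,0.05,0.05,0.05,0.048,0.048,0.047,0.044,0.039,0.035,0.031,0.027,0.024,0.018
-7.0,0.066,0.066,0.066,0.066,0.064,0.064,0.061,0.056,0.05,0.043,0.038,0.032,0.028,0.02
-6.0,0.096,0.092,0.092,0.091,0.088,0.088,0.083,0.073,0.063,0.054,0.045,0.038,0.032,0.023
-5.0,0.135,0.135,0.135,0.134,0.128,0.124,0.116,0.099,0.082,0.067,0.054,0.044,0.036,0.025
-4.0,0.218,0.213,0.214,0.208,0.198,0.189,0.172,0.138,0.107,0.083,0.064,0.051,0.041,0.027
-3.0,0.377,0.386,0.376,0.365,0.348,0.312,0.269,0.196,0.139,0.102,0.076,0.057,0.045,0.029
-2.0,0.854,0.883,0.84,0.771,0.716,0.571,0.449,0.274,0.177,0.12,0.085,0.064,0.048,0.031
-1.5,1.6,1.545,1.429,1.275,1.113,0.809,0.578,0.319,0.194,0.127,0.09,0.066,0.05,0.031
-1.0,3.451,3.405,2.899,2.336,1.845,1.124,0.731,0.362,0.209,0.135,0.093,0.067,0.051,0.031
-0.75,6.703,5.825,4.517,3.321,2.385,1.309,0.807,0.38,0.216,0.137,0.095,0.068,0.052,0.032
-0.5,14.964,11.884,7.533,4.627,2.987,1.481,0.862,0.389,0.22,0.139,0.095,0.069,0.052,0.032
0.0,,57.034,15.555,6.778,3.749,1.656,0.919,0.402,0.223,0.14,0.096,0.069,0.052,0.032
0.5,,11.653,7.534,4.643,3.001,1.483,0.868,0.393,0.22,0.139,0.095,0.069,0.052,0.032
0.75,,5.672,4.537,3.316,2.386,1.314,0.805,0.379,0.215,0.137,0.094,0.068,0.051,0.032
1.0,,3.313,2.891,2.36,1.838,1.13,0.733,0.362,0.21,0.135,0.093,0.068,0.051,0.032
1.5,,1.488,1.395,1.27,1.111,0.807,0.578,0.321,0.194,0.128,0.09,0.066,0.05,0.031
2.0,,0.831,0.798,0.764,0.704,0.577,0.45,0.273,0.176,0.12,0.085,0.064,0.049,0.031
3.0,,0.368,0.364,0.346,0.342,0.311,0.27,0.193,0.14,0.101,0.075,0.058,0.045,0.029
4.0,,0.206,0.202,0.198,0.145,0.184,0.171,0.138,0.107,0.083,0.065,0.051,0.041,0.027
5.0,,0.127,0.126,0.126,0.093,0.12,0.114,0.198,0.083,0.067,0.054,0.044,0.036,0.025
6.0,,0.087,0.087,0.087,0.064,0.083,0.08,0.073,0.063,0.054,0.045,0.038,0.032,0.023
7.0,,0.065,0.064,0.062,0.047,0.061,0.059,0.055,0.05,0.044,0.038,0.032,0.027,0.02
8.0,,0.049,0.047,0.048,0.035,0.046,0.045,0.043,0.039,0.035,0.031,0.027,0.024,0.018
10.0,,0.029,0.029,0.03,0.022,0.029,0.028,0.027,0.026,0.024,0.022,0.02,0.018,0.014
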