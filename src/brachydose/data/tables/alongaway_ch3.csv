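z_cm,0.0,0.25,0.5,0.75,1.0,1.5,2.0,3.0,4.0,5.0,6.0,7.0,8.0,10.0
-10.0,0.032,0.032,0.031,0.03,0.03,0.03,0.03,0.028,0.026,0.024,0.022,0.02,0.018,0.014
-8.0,0.048,0.05,0.049,0.049,0.048,0.048,0.047,0.044,0.04,0.036,0.032,0.027,0.024,0.018
-7.0,0.065,0.068,0.066,0.066,0.064,0.064,0.062,0.056,0.05,0.044,0.038,0.032,0.028,0.02
-6.0,0.089,0.093,0.093,0.091,0.087,0.087,0.083,0.074,0.063,0.054,0.045,0.038,0.032,0.023
-5.0,0.133,0.134,0.133,0.133,0.127,0.125,0.116,0.1,0.082,0.067,0.054,0.044,0.036,0.025
-4.0,0.216,0.215,0.212,0.208,0.197,0.189,0.174,0.138,0.107,0.083,0.064,0.051,0.041,0.027
-3.0,0.347,0.387,0.38,0.365,0.351,0.313,0.272,0.196,0.139,0.101,0.076,0.058,0.045,0.029
-2.0,0.85,0.876,0.836,0.779,0.716,0.575,0.449,0.274,0.177,0.12,0.086,0.063,0.048,0.031
-1.5,1.568,1.561,1.439,1.288,1.114,0.812,0.58,0.319,0.194,0.128,0.09,0.066,0.05,0.031
-1.0,3.695,3.4,2.959,2.385,1.87,1.131,0.731,0.361,0.209,0.135,0.093,0.067,0.051,0.032
-0.75,6.433,5.947,4.595,3.305,2.382,1.31,0.803,0.376,0.214,0.137,0.094,0.068,0.051,0.032
-0.5,15.054,12.252,7.608,4.589,3.006,1.484,0.865,0.391,0.22,0.139,0.095,0.069,0.052,0.032
0.0,,55.069,15.334,6.716,3.775,1.649,0.918,0.403,0.223,0.141,0.096,0.069,0.052,0.032
0.5,,12.025,7.606,4.602,2.995,1.483,0.864,0.391,0.22,0.139,0.095,0.069,0.052,0.032
0.75,,5.862,4.605,3.334,2.395,1.313,0.802,0.378,0.215,0.137,0.094,0.068,0.051,0.032
1.0,,3.254,2.92,2.378,1.871,1.129,0.736,0.359,0.209,0.135,0.093,0.068,0.051,0.032
1.5,,1.472,1.396,1.274,1.123,0.809,0.582,0.319,0.194,0.127,0.09,0.066,0.05,0.031
2.0,,0.826,0.798,0.763,0.712,0.577,0.45,0.275,0.176,0.12,0.086,0.063,0.048,0.03
3.0,,0.367,0.354,0.349,0.342,0.311,0.271,0.195,0.14,0.102,0.075,0.058,0.045,0.029
4.0,,0.199,0.198,0.196,0.144,0.184,0.173,0.139,0.107,0.083,0.065,0.051,0.04,0.027
5.0,,0.128,0.125,0.125,0.09,0.12,0.115,0.198,0.082,0.067,0.054,0.044,0.036,0.025
6.0,,0.086,0.086,0.085,0.063,0.083,0.081,0.074,0.064,0.054,0.045,0.038,0.032,0.022
7.0,,0.062,0.063,0.063,0.046,0.061,0.059,0.055,0.05,0.044,0.038,0.032,0.028,0.02
8.0,,0.047,0.046,0.046,0.035,0.046,0.045,0.043,0.039,0.035,0.032,0.028,0.024,0.018
10.0,,0.03,0.029,0.029,0.021,0.029,0.028,0.027,0.026,0.024,0.022,0.02,0.018,0.014
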