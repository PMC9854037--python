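energy_mev,mu_rho,mu_en_rho,f_compton,f_photo,f_pair
0.01,166.65471869503483,166.47830264508332,0.001078814661376845,0.99892118533862317,0
0.014999999999999999,55.76280514995743,55.591115513615136,0.0031662519009039735,0.99683374809909597,0
0.02,25.089689158243424,24.92246493501802,0.0069143211687945098,0.99308567883120558,0
0.029999999999999999,7.9907940799689339,7.8317968886454503,0.020989834830008363,0.97901016516999162,0
0.040000000000000001,3.5489361093755303,3.3973412768964075,0.045777220209589499,0.95422277979041048,0
0.050000000000000003,1.9165046661343053,1.7716027427895644,0.082245225587439102,0.91775477441256093,0
0.059999999999999998,1.1808292723349074,1.0420062569092303,0.12970851240349554,0.87029148759650454,0
0.080000000000000002,0.58495355287915429,0.45675202434430656,0.24824144710280058,0.75175855289719951,0
0.10000000000000001,0.36646032496397773,0.24722736543172849,0.3774537839394031,0.62254621606059701,0
0.14999999999999999,0.1948831178113444,0.092965614163746602,0.63898123915488503,0.36101876084511497,0
0.20000000000000001,0.14539638475105343,0.055977721672964928,0.78479035720271051,0.21520964279728941,0
0.29999999999999999,0.10976991472177998,0.037305946747156912,0.90387911762318174,0.096120882376818234,0
0.40000000000000002,0.093986859670743703,0.032614964975627547,0.94584148368650844,0.054158516313491577,0
0.5,0.084167202455330464,0.030703761536609194,0.96442899193722575,0.035571008062774211,0
0.59999999999999998,0.077083566182907182,0.02958999906384939,0.97414358606935025,0.025856413930649809,0
0.80000000000000004,0.067043989219541147,0.028041176183238363,0.98378244827832106,0.016217551721678922,0
1,0.06000473708315289,0.026805323363215294,0.98807527321009114,0.011924726789908855,0
1.25,0.053551181081673463,0.025489444818421265,0.98978994751046367,0.010150410908316455,5.9641581219969689e-05
1.5,0.048871869506211862,0.024533792425406216,0.98551632953794233,0.013881482426215305,0.00060218803584236947
2,0.042665676466946703,0.023390144430119577,0.96295553914231313,0.031136434996593999,0.0059080258610928965
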