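energy_mev,mu_rho,mu_en_rho,f_compton,f_photo,f_pair
0.01,4.9309229658406837,4.742,0.039046570751691684,0.9609534292483084,0
0.014999999999999999,1.5178614758170121,1.3340000000000001,0.12456745710658569,0.87543254289341432,0
0.02,0.71797948976768156,0.53890000000000005,0.25874946009925065,0.74125053990074929,0
0.029999999999999999,0.32396920710120003,0.1537,0.55442382962197467,0.44557617037802527,0
0.040000000000000001,0.23067206222136624,0.068330000000000002,0.75422211176934995,0.24577788823065008,0
0.050000000000000003,0.1961546630866669,0.040980000000000003,0.86053512384116138,0.13946487615883868,0
0.059999999999999998,0.17907479443550084,0.03041,0.91594161004280539,0.084058389957194626,0
0.080000000000000002,0.16136030325057263,0.024070000000000001,0.96370838354956556,0.03629161645043448,0
0.10000000000000001,0.15093591263087935,0.02325,0.98139721647823397,0.01860278352176593,0
0.14999999999999999,0.13410288731367706,0.02496,0.99442230885865412,0.0055776911413458492,0
0.20000000000000001,0.12247794852488517,0.026720000000000001,0.99769092942517956,0.0023090705748204129,0
0.29999999999999999,0.10632125992001376,0.028719999999999999,0.99935600497405908,0.00064399502594087517,0
0.40000000000000002,0.095212820391056524,0.029489999999999999,0.99985432116092832,0.00014567883907157386,0
0.5,0.086928024628584344,0.029659999999999999,1,0,0
0.59999999999999998,0.08041395731018107,0.029530000000000001,1,0,0
0.80000000000000004,0.070632662716483982,0.028819999999999998,1,0,0
1,0.063492471009514689,0.027890000000000002,1,0,0
1.25,0.056763118079993291,0.02666,0.99998275291322969,0,1.7247086770283978e-05
1.5,0.051587607747936949,0.02547,0.99982513234915682,0,0.00017486765084316408
2,0.04409205995744267,0.023449999999999999,0.99786351370329451,0.00038412188897016903,0.0017523644077352843
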