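energy_mev,mu_rho,mu_en_rho,f_compton,f_photo,f_pair
0.01,166.38073359380252,166.20435197348499,0.0010803802941651674,0.99891961970583476,0
0.014999999999999999,55.671298343255188,55.499642214132578,0.0031708373167064772,0.99682916268329347,0
0.02,25.048653354319416,24.88146176683664,0.0069242968929066296,0.99307570310709337,0
0.029999999999999999,7.9778877577752736,7.8189215965939258,0.021019688347118492,0.97898031165288146,0
0.040000000000000001,3.543331641954298,3.3917663949613073,0.04584067769221141,0.95415932230778866,0
0.050000000000000003,1.9135795009726513,1.7687058569153602,0.082354872897997117,0.91764512710200297,0
0.059999999999999998,1.1791082610439823,1.0403123385365165,0.12987248221854081,0.87012751778145914,0
0.080000000000000002,0.58420157405045492,0.45602506552771777,0.24851247163067294,0.75148752836932697,0
0.10000000000000001,0.36605790670855853,0.24684821686837599,0.37779498456268329,0.62220501543731666,0
0.14999999999999999,0.19474303687738426,0.092845423610226518,0.63931607151441805,0.36068392848558201,0
0.20000000000000001,0.14532262393667206,0.055921411945623681,0.78503545139821318,0.21496454860178693,0
0.29999999999999999,0.10973318808561447,0.037283362293046754,0.9040051757054326,0.095994824294567335,0
0.40000000000000002,0.093961134076286257,0.032601216816744202,0.94591580292811772,0.054084197071882271,0
0.5,0.084146433786584499,0.030693426877149658,0.96447876230752383,0.035521237692476275,0
0.59999999999999998,0.077065631570834042,0.029581333371094753,0.97418012784003216,0.025819872159967915,0
0.80000000000000004,0.067029327770180808,0.028034126584264445,0.98380559431353076,0.016194405686469279,0
1,0.059991988622217836,0.026799054152120961,0.98809236659262245,0.01190763340737754,0
1.25,0.053539940952912021,0.025483681262280899,0.98980453363556142,0.010135834922789503,5.9631441649071812e-05
1.5,0.048861342166190175,0.024528014942818144,0.98553628597860354,0.013861625043253308,0.00060208897814320594
2,0.042655376371332342,0.023383606177679109,0.96300008901718515,0.031092703307332593,0.0059072076754823786
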