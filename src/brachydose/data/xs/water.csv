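energy_mev,mu_rho,mu_en_rho,f_compton,f_photo,f_pair
0.01,5.1540811441885399,4.944,0.041539587881391435,0.95846041211860855,0
0.014999999999999999,1.5784527992663635,1.3740000000000001,0.13320099134145205,0.86679900865854798,0
0.02,0.74943526099743685,0.55030000000000001,0.27565107267235156,0.72434892732764844,0
0.029999999999999999,0.34503828234551526,0.15570000000000001,0.57886948641368308,0.42113051358631687,0
0.040000000000000001,0.24999334733169504,0.069470000000000004,0.77387020575068566,0.22612979424931434,0
0.050000000000000003,0.21478324478554217,0.042229999999999997,0.8739149288912379,0.12608507110876213,0
0.059999999999999998,0.19721431198206629,0.031899999999999998,0.92483901115208245,0.075160988847917637,0
0.080000000000000002,0.17863594966116528,0.02597,0.96800097471204904,0.031999025287951066,0
0.10000000000000001,0.16744592798333313,0.02546,0.98370558146262888,0.016294418537371132,0
0.14999999999999999,0.14900620100614828,0.027640000000000001,0.99519220178210199,0.0048077982178981096,0
0.20000000000000001,0.13615223365400425,0.029669999999999998,0.99800214785450592,0.001997852145493965,0
0.29999999999999999,0.11821211065962453,0.031919999999999997,0.99949514398164396,0.00050485601835596132,0
0.40000000000000002,0.1058733609646717,0.03279,0.99987975963583131,0.00012024036416873637,0
0.5,0.096663414078638807,0.032989999999999998,1,0,0
0.59999999999999998,0.089419812383727051,0.032840000000000001,1,0,0
0.80000000000000004,0.078543074604679575,0.032059999999999998,1,0,0
1,0.070603226546235603,0.031029999999999999,1,0,0
1.25,0.063120116286055336,0.029649999999999999,0.99998453244389929,0,1.5467556100706336e-05
1.5,0.057364058795932461,0.028330000000000001,0.99984317240209486,0,0.0001568275979051582
2,0.049033840233086913,0.026079999999999999,0.99778723627263433,0.00064132879432897037,0.0015714349330367536
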