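energy_mev,mu_rho,mu_en_rho,f_compton,f_photo,f_pair
0.01,193.01014948357258,192.83675759915405,0.00091553506100637159,0.99908446493899361,0
0.014999999999999999,64.560928260947748,64.392181768841724,0.0026878868529082458,0.99731211314709167,0
0.02,29.03177945080364,28.867421824649764,0.005873024954315029,0.99412697504568492,0
0.029999999999999999,9.2265705941278338,9.0702989701548109,0.017866904830379893,0.98213309516962011,0
0.040000000000000001,4.0823427976527862,3.9333466395430938,0.039113691010828004,0.96088630898917204,0
0.050000000000000003,2.1922920030803708,2.049874022678269,0.07066638093917274,0.92933361906082723,0
0.059999999999999998,1.3409173267354777,1.2044740481792839,0.11226496863064701,0.88773503136935294,0
0.080000000000000002,0.65209039444916539,0.52608652675062062,0.21886612418281004,0.78113387581718996,0
0.10000000000000001,0.40021108258661409,0.28302204256574026,0.3396974664058991,0.66030253359410096,0
0.14999999999999999,0.20388821814241848,0.10371780837786451,0.60028966812313433,0.39971033187686561,0
0.20000000000000001,0.14839471641289764,0.06050888914517065,0.75575234042590789,0.24424765957409214,0
0.29999999999999999,0.10973968633884999,0.038517912792647192,0.88862931891130137,0.11137068108869867,0
0.40000000000000002,0.093268918006570181,0.0329490748038394,0.9367834962582462,0.063216503741753707,0
0.5,0.083249746557612192,0.030702788551566485,0.95834283986310109,0.041657160136898949,0
0.59999999999999998,0.076111922464191378,0.029432501273241717,0.96966731094976022,0.030332689050239725,0
0.80000000000000004,0.066085497949568639,0.027751280332486871,0.98094221220064282,0.019057787799357118,0
1,0.059101681458625002,0.026471379918193885,0.98597613726135869,0.014023862738641278,0
1.25,0.052728734013468719,0.025148038651126314,0.9879965337041251,0.011940949111938376,6.2517183936424697e-05
1.5,0.048154591079189443,0.024233723055426148,0.98305032416493798,0.016318890010817457,0.00063078582424460684
2,0.042179819539493325,0.023234713218649169,0.95735018793954618,0.036481805103559396,0.0061680069568942515
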