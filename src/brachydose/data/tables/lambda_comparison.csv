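source,code,this_work,lambda_cgy_h_u,uncertainty
GZP3_ch12,Geant4,True,1.115,0.004
GZP3_ch12,EGSnrc,True,1.112,0.004
GZP3_ch3,Geant4,True,1.116,0.004
GZP3_ch3,EGSnrc,True,1.113,0.004
GZP6,MCNP,False,1.104,0.003
BEBIG,Geant4,False,1.084,0.005
Flexisource,Geant4,False,1.085,0.003
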