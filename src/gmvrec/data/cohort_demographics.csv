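subject_id,age,sex,side,lesion_location,lesion_volume_cc,nihss,mrs,mmse
p01,77,m,L,SM1,2.7,4,2,29
p02,50,m,R,"SM1, PMC",14.8,7,4,30
p03,78,m,R,SM1,2.8,5,3,27
p05,80,m,L,SM1,2.5,2,4,27
p06,53,f,R,"SM1, PMC, PPC, SII",22.0,6,2,28
p07,78,f,R,"SM1, PMC, PPC",17.7,4,3,30
p09,70,f,R,"SM1, PMC, PPC, SII",75.5,3,2,26
p11,41,f,R,"SM1, SII",5.9,3,2,27
p12,54,m,R,SM1,8.2,4,1,30
p15,54,m,L,"SM1, PPC",22.1,6,3,30
p16,73,m,R,SM1,2.7,4,2,30
p17,58,m,L,SM1,18.3,4,3,30
p20,70,m,L,"SM1, PPC, SII",67.9,6,3,30
p24,74,m,R,"SM1, PPC",24.9,4,1,30
p25,49,m,R,"SM1, PPC, SII",70.4,3,2,28
p26,44,m,L,SM1,2.1,3,1,30
p30,63,m,L,SM1,9.7,4,2,26
p31,63,m,L,SM1,0.8,5,3,27
p33,75,m,R,SM1,12.1,3,2,30
p35,78,m,L,SM1,0.7,5,2,26
p36,60,m,L,"SM1, PMC",3.6,4,3,27
p37,75,m,R,"SM1, PPC",63.6,4,3,30
p38,77,m,L,"SM1, PPC",3.4,5,2,30
p41,51,m,R,SM1,0.6,2,3,30
p42,64,m,R,SM1,1.9,1,2,30
p43,82,m,L,"SM1, PPC",6.7,3,2,28
p44,67,m,R,"SM1, PMC, PPC",141.7,11,4,27
p45,53,m,R,"SM1, PMC, PPC, SII",78.8,14,4,27
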