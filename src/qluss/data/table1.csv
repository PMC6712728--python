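Patients,QLUSS,qLUSS,%LUSS,cLUSS,nLUSS,EVLW
1,2.26,9,16,14,23,8.00
2,15.72,12,27,24,19,10.00
3,31.31,18,38,24,14,17.00
4,15.00,9,16,18,16,10.00
5,22.24,12,26,22,35,12.00
6,28.19,14,44,24,29,16.00
7,25.17,22,46,26,23,20.70
8,37.66,14,25,17,19,14.00
9,13.46,11,13,14,9,11.70
10,22.21,9,36,13,24,12.00
11,10.15,9,12,11,28,8.00
12,10.55,12,11,20,14,10.00
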