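,1850,1875,1900,1925,1950,1975
I01,8,10,10,11,11,11
I02,4,6,7,7,8,8
I03,3,4,4,4,4,5
I04,2,3,4,4,5,6
I05,4,5,5,6,6,6
I06,2,2,2,2,2,2
I07,21,22,25,27,28,30
I08,3,3,4,4,5,6
I09,0,0,0,0,0,0
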