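code,name,lat,lon,area_km2,age_ma,altitude_m,tri,harbor
I01,Island 1,15.818678987593222,-24.80698652189545,102.14364476723877,12.56041799560911,1809.4594739309202,160.7774122161559,0
I02,Island 2,17.165222646228607,-25.35284266214938,786.0152896589309,2.9751949660196706,449.009409193682,26.49659896882664,1
I03,Island 3,15.553007735081186,-24.679554433017284,73.96257168356078,9.116030472313346,1843.6918044980514,126.32026275101599,0
I04,Island 4,15.764821711707496,-23.794697850662264,14.986897891414205,15.931206705387837,2172.2384225960445,163.00754160192358,0
I05,Island 5,16.17323883629309,-23.71734575291321,115.86853999757611,5.522237184936341,756.9102543095189,88.7652075167771,0
I06,Island 6,14.82853026511458,-23.70182738921436,26.102365479090658,10.204899230748781,1995.9671437674126,132.28436166435839,0
I07,Island 7,14.953654737269368,-24.875525110128468,17.42301442536357,22.176447975643136,2183.856420211823,213.39114253008472,1
I08,Island 8,15.34871120791024,-23.247564751214227,147.74924278721087,10.342671843674689,1794.5600416485495,135.2250744712565,0
I09,Island 9,15.461327940991982,-23.223429486290215,292.6704486558145,4.021730999106096,728.7620539990553,53.28163991855944,0
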