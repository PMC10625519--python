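zone,year,class,method,count
a,2017,maize,I,4234
a,2018,maize,I,4965
a,2019,maize,I,5752
a,2020,maize,I,1561
a,2017,non_maize_crop,I,9703
a,2018,non_maize_crop,I,10984
a,2019,non_maize_crop,I,8960
a,2020,non_maize_crop,I,2430
a,2017,non_cropland,IV,3183
a,2018,non_cropland,IV,5061
a,2019,non_cropland,IV,7495
a,2020,non_cropland,IV,465
b,2020,maize,I,2061
b,2020,non_maize_crop,I,1936
b,2020,non_cropland,IV,1655
c,2020,maize,I,1035
c,2020,non_maize_crop,I,128
c,2020,non_maize_crop,II,568
c,2020,non_cropland,IV,1134
d,2020,maize,I,663
d,2020,non_maize_crop,II,678
d,2020,non_cropland,IV,856
e,2020,maize,III,745
e,2020,non_cropland,IV,1361
e,2021,maize,I,523
e,2021,non_maize_crop,I,1119
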