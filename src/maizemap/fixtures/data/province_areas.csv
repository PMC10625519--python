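province,total_area_km2,year,predicted_km2,yearbook_km2
Beijing,16406,2017,387,497
Beijing,16406,2018,388,401
Beijing,16406,2019,218,337
Beijing,16406,2020,393,356
Beijing,16406,2021,262,428
Tianjin,11917,2017,1794,2014
Tianjin,11917,2018,1688,1868
Tianjin,11917,2019,1009,1808
Tianjin,11917,2020,1726,1788
Tianjin,11917,2021,706,1856
Hebei,188545,2017,42067,35441
Hebei,188545,2018,42003,34377
Hebei,188545,2019,38105,34082
Hebei,188545,2020,41698,34171
Hebei,188545,2021,30715,34541
Shanxi,156698,2017,9826,18069
Shanxi,156698,2018,16334,17477
Shanxi,156698,2019,8070,17150
Shanxi,156698,2020,15951,17422
Shanxi,156698,2021,5057,17726
Neimenggu,1145499,2017,32557,37163
Neimenggu,1145499,2018,31390,37421
Neimenggu,1145499,2019,38456,37763
Neimenggu,1145499,2020,36259,38239
Neimenggu,1145499,2021,33779,42046
Liaoning,148379,2017,16481,26920
Liaoning,148379,2018,17558,27140
Liaoning,148379,2019,23409,26750
Liaoning,148379,2020,17721,26993
Liaoning,148379,2021,23763,27242
Jilin,191202,2017,26314,41640
Jilin,191202,2018,34633,42315
Jilin,191202,2019,41232,42196
Jilin,191202,2020,35317,42872
Jilin,191202,2021,43616,44012
Heilongjiang,452538,2017,66894,58628
Heilongjiang,452538,2018,68200,63178
Heilongjiang,452538,2019,66196,58746
Heilongjiang,452538,2020,56361,54806
Heilongjiang,452538,2021,68605,65242
Shanghai,8359,2017,48,30
Shanghai,8359,2018,105,18
Shanghai,8359,2019,67,16
Shanghai,8359,2020,46,12
Shanghai,8359,2021,7,10
Jiangsu,106600,2017,1309,5432
Jiangsu,106600,2018,3911,5158
Jiangsu,106600,2019,4647,5042
Jiangsu,106600,2020,2716,5097
Jiangsu,106600,2021,4896,5006
Zhejiang,105506,2017,47,519
Zhejiang,105506,2018,215,493
Zhejiang,105506,2019,123,764
Zhejiang,105506,2020,235,632
Zhejiang,105506,2021,23,580
Anhui,140140,2017,3235,11601
Anhui,140140,2018,12019,11386
Anhui,140140,2019,12473,11965
Anhui,140140,2020,13154,12347
Anhui,140140,2021,19757,12527
Fujian,123951,2017,331,268
Fujian,123951,2018,556,288
Fujian,123951,2019,512,305
Fujian,123951,2020,405,330
Fujian,123951,2021,227,340
Jiangxi,166836,2017,220,357
Jiangxi,166836,2018,599,350
Jiangxi,166836,2019,2316,465
Jiangxi,166836,2020,411,476
Jiangxi,166836,2021,385,509
Shandong,157901,2017,32620,40001
Shandong,157901,2018,33118,39347
Shandong,157901,2019,34725,38465
Shandong,157901,2020,34876,38710
Shandong,157901,2021,24608,38970
Henan,165664,2017,48293,39989
Henan,165664,2018,61487,39190
Henan,165664,2019,60614,38013
Henan,165664,2020,61387,38180
Henan,165664,2021,38733,38533
Hubei,185937,2017,2149,7948
Hubei,185937,2018,2972,7812
Hubei,185937,2019,2951,7275
Hubei,185937,2020,2811,7519
Hubei,185937,2021,9190,7627
Hunan,211836,2017,4083,3658
Hunan,211836,2018,784,3592
Hunan,211836,2019,1219,3866
Hunan,211836,2020,2140,3843
Hunan,211836,2021,696,3976
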