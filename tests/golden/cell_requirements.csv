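lon,lat,excess_n_kg,excess_p_kg,limitation,sizing_nutrient,biomass_t
0.5,-4.5,1003,266,P_limited,P,30.5147361
1.5,-4.5,160,16,N_limited,N,2.536764475
2.5,-4.5,750,41,N_limited,N,11.89108348
3.5,-4.5,2427,1071,P_limited,P,122.8619638
4.5,-4.5,6978,1076,P_limited,P,123.435549
5.5,-4.5,2269,271,N_limited,N,35.97449121
6.5,-4.5,3667,779,P_limited,P,89.3645843
7.5,-4.5,4121,1374,P_limited,P,157.6212308
8.5,-4.5,1907,-216,N_limited,N,30.23506159
9.5,-4.5,5615,870,P_limited,P,99.80383612
0.5,-3.5,2191,233,N_limited,N,34.73781853
1.5,-3.5,3825,216,N_limited,N,60.64452573
2.5,-3.5,205,14,N_limited,N,3.250229483
3.5,-3.5,974,186,P_limited,P,21.33737186
4.5,-3.5,674,62,N_limited,N,10.68612035
5.5,-3.5,3811,1421,P_limited,P,163.0129323
6.5,-3.5,23821,3630,P_limited,P,416.4229024
7.5,-3.5,32734,3088,N_limited,N,518.990302
8.5,-3.5,761,62,N_limited,N,12.06548603
9.5,-3.5,1506,233,P_limited,P,26.72907335
0.5,-2.5,12270,3037,P_limited,P,348.39569
1.5,-2.5,12282,1877,P_limited,P,215.3239085
2.5,-2.5,7036,2789,P_limited,P,319.9458609
3.5,-2.5,,,none,,0
4.5,-2.5,,,none,,0
5.5,-2.5,2925,400,N_limited,N,46.37522556
6.5,-2.5,3407,448,N_limited,N,54.01722854
7.5,-2.5,2641,626,P_limited,P,71.81287519
8.5,-2.5,10501,767,N_limited,N,166.4910234
9.5,-2.5,2110,269,N_limited,N,33.45358151
0.5,-1.5,31414,5139,P_limited,P,589.5309354
1.5,-1.5,201,14,N_limited,N,3.186810372
2.5,-1.5,89008,9103,N_limited,N,1411.202077
3.5,-1.5,,,none,,0
4.5,-1.5,,,none,,0
5.5,-1.5,3193,327,N_limited,N,50.62430605
6.5,-1.5,833,145,P_limited,P,16.63397269
7.5,-1.5,292,88,P_limited,P,10.09510067
8.5,-1.5,26681,2575,N_limited,N,423.021331
9.5,-1.5,7047,2422,P_limited,P,277.8447024
0.5,-0.5,42082,3236,N_limited,N,667.2007665
1.5,-0.5,4116,365,N_limited,N,65.25826612
2.5,-0.5,13304,2093,P_limited,P,240.102792
3.5,-0.5,11772,464,N_limited,N,186.6424462
4.5,-0.5,404,35,N_limited,N,6.405330299
5.5,-0.5,7537,923,N_limited,N,119.4974615
6.5,-0.5,44025,2098,N_limited,N,698.0066
7.5,-0.5,2827,506,P_limited,P,58.04682882
8.5,-0.5,17618,1958,N_limited,N,279.3294782
9.5,-0.5,1731,238,N_limited,N,27.44462066
0.5,0.5,1227,82,N_limited,N,19.45381257
1.5,0.5,12936,904,N_limited,N,205.0974078
2.5,0.5,11313,2370,P_limited,P,271.8794156
3.5,0.5,8924,283,N_limited,N,141.4880386
4.5,0.5,585,51,N_limited,N,9.275045111
5.5,0.5,114994,14774,N_limited,N,1823.204338
6.5,0.5,459,44,N_limited,N,7.277343087
7.5,0.5,8941,826,N_limited,N,141.7575698
8.5,0.5,8410,273,N_limited,N,133.3386827
9.5,0.5,3661,-532,N_limited,N,58.04434214
0.5,1.5,22007,4693,P_limited,P,538.3671298
1.5,1.5,29777,1873,N_limited,N,472.1077236
2.5,1.5,19,1,N_limited,N,0.3012407814
3.5,1.5,356,25,N_limited,N,5.644300957
4.5,1.5,3400,564,P_limited,P,64.7004179
5.5,1.5,1205,125,N_limited,N,19.10500745
6.5,1.5,9016,1903,P_limited,P,218.3065519
7.5,1.5,3536,381,N_limited,N,56.0624949
8.5,1.5,8775,1277,P_limited,P,146.4936767
9.5,1.5,1728,141,N_limited,N,27.39705633
0.5,2.5,10646,1575,P_limited,P,180.6793585
1.5,2.5,865,-90,N_limited,N,13.71438294
2.5,2.5,1922,-281,N_limited,N,30.47288325
3.5,2.5,2565,744,P_limited,P,85.34948744
4.5,2.5,1017,97,N_limited,N,16.12430919
5.5,2.5,1499,197,N_limited,N,23.76631217
6.5,2.5,15894,2233,P_limited,P,256.1631794
7.5,2.5,5340,821,P_limited,P,94.18270052
8.5,2.5,946,75,N_limited,N,14.99861996
9.5,2.5,706,134,P_limited,P,15.3720851
0.5,3.5,741,64,N_limited,N,11.74839047
1.5,3.5,571,-148,N_limited,N,9.05307822
2.5,3.5,40744,-3279,N_limited,N,645.9870735
3.5,3.5,3355,370,N_limited,N,53.19278008
4.5,3.5,528,59,N_limited,N,8.371322767
5.5,3.5,1413,112,N_limited,N,22.40280127
6.5,3.5,13026,12792,P_limited,P,1467.460542
7.5,3.5,1376,206,P_limited,P,23.63171292
8.5,3.5,10878,1097,N_limited,N,172.4682747
9.5,3.5,4500,790,P_limited,P,90.62647188
0.5,4.5,1937,86,N_limited,N,30.71070492
1.5,4.5,1659,222,N_limited,N,26.30307665
2.5,4.5,397,90,P_limited,P,10.32453477
3.5,4.5,4809,441,N_limited,N,76.24562725
4.5,4.5,12961,1278,N_limited,N,205.4937772
5.5,4.5,8568,2256,P_limited,P,258.8016716
6.5,4.5,10637,655,N_limited,N,168.6472732
7.5,4.5,118,7,N_limited,N,1.8708638
8.5,4.5,2305,268,N_limited,N,36.54526322
9.5,4.5,1973,432,P_limited,P,49.5577669
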