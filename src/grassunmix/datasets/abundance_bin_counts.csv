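bin_low,bin_high,herbaceous_2018,herbaceous_2022,forbs_2018,forbs_2022,bare_soil_2018,bare_soil_2022
0.0,0.1,39728,110840,67708,84151,223164,168489
0.1,0.2,19898,22713,27598,21243,35489,35859
0.2,0.3,26403,24009,33656,24339,22714,27832
0.3,0.4,31537,24109,37939,26805,13456,21918
0.4,0.5,35391,23736,39299,27064,7478,17256
0.5,0.6,36291,22718,35959,26365,4516,13836
0.6,0.7,34747,22353,27703,23765,3129,10770
0.7,0.8,32547,20907,19619,20275,2439,8032
0.8,0.9,30098,19823,12790,16726,1965,5188
0.9,1.0,172720,168152,157089,188627,145010,150180
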