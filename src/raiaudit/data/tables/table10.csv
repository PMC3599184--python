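quarter,auto_all_clinical_ccc,auto_all_clinical_ltc,auto_mood16_ccc,auto_mood16_ltc,auto_adl20_ccc,auto_adl20_ltc,n_ccc,n_ltc
1996_3,0.7,,34.8,,34.2,,3853,
1996_4,2.2,,35.3,,36.0,,3600,
1997_1,1.4,,32.2,,33.5,,3213,
1997_2,1.1,,26.4,,29.8,,3184,
1997_3,1.0,,32.7,,34.4,,3331,
1997_4,1.7,,36.7,,39.1,,3329,
1998_2,1.2,,36.8,,38.9,,3292,
1998_3,1.0,,33.6,,34.9,,3290,
1998_4,0.9,,34.2,,36.1,,3259,
1999_1,0.7,,38.1,,41.4,,3131,
1999_2,1.1,,38.0,,41.4,,3172,
1999_3,0.9,,35.4,,37.7,,3242,
1999_4,1.0,,37.1,,39.2,,3138,
2000_1,1.0,,35.8,,37.6,,3104,
2000_2,0.5,,35.8,,37.8,,3080,
2000_3,0.9,,34.6,,38.7,,3133,
2000_4,1.2,,35.4,,38.3,,2961,
2001_1,1.3,,35.3,,37.9,,2915,
2001_2,1.3,,33.2,,35.4,,2965,
2001_3,1.2,,34.4,,37.8,,3059,
2001_4,0.4,,35.9,,38.2,,3103,
2002_1,0.7,,35.7,,37.4,,3168,
2002_2,0.3,,35.5,,38.1,,3030,
2002_3,0.5,,36.9,,37.6,,3041,
2002_4,0.5,,38.2,,39.5,,3042,
2003_1,0.4,,41.5,,39.8,,2931,
2003_2,0.4,,31.2,,33.5,,2808,
2003_3,1.0,,36.8,,38.2,,2726,
2003_4,2.4,,41.5,,45.1,,2720,
2004_1,1.7,,43.1,,45.9,,2715,
2004_2,1.1,,42.5,,44.6,,2722,
2004_3,0.8,,44.4,,45.4,,2738,
2004_4,1.1,,45.8,,45.5,,2657,
2005_1,0.7,,46.0,,47.5,,2631,
2005_2,0.7,,44.8,,45.9,,2552,
2005_3,0.8,,43.3,,44.9,,2503,
2005_4,0.6,0.5,45.8,28.6,49.0,39.3,2500,880
2006_1,0.4,0.0,43.7,15.4,44.4,26.0,2461,1941
2006_2,0.6,0.2,47.0,16.6,48.1,28.3,2478,1960
2006_3,0.7,0.2,48.6,20.0,51.2,31.2,2541,4209
2006_4,0.6,0.3,47.7,19.3,51.2,30.5,2516,9708
2007_1,0.7,0.3,50.0,18.9,52.5,29.8,2480,9699
2007_2,0.9,0.2,50.0,18.8,53.0,30.1,2457,9732
2007_3,0.6,0.1,50.6,20.4,51.5,32.4,2483,10262
2007_4,2.0,0.1,46.4,22.0,49.8,32.5,2500,12887
2008_1,1.2,0.2,47.2,22.4,48.8,33.9,2479,15044
2008_2,1.6,0.1,47.7,24.9,49.6,35.0,2404,15056
2008_3,0.9,0.1,48.6,25.5,48.5,34.9,2469,19116
2008_4,0.7,0.2,48.1,26.1,51.2,34.4,2424,20291
2009_1,0.3,0.2,48.8,26.9,49.3,36.1,2394,20075
2009_2,1.2,0.2,48.1,28.2,50.1,36.3,2302,19721
2009_3,0.7,0.1,48.0,24.7,48.9,31.2,2282,26965
2009_4,0.6,0.1,46.6,20.6,49.0,25.9,2288,42271
2010_1,0.5,0.1,44.2,19.7,46.6,24.6,2237,51059
2010_2,0.4,0.1,45.5,20.5,46.0,24.8,2250,52614
2010_3,0.5,0.0,46.6,20.8,44.5,24.6,2243,52750
2010_4,0.8,0.0,48.3,21.1,48.2,24.6,2105,52064
2011_1,0.6,0.0,46.7,20.8,48.6,23.5,2021,51771
intercept,0.5,0.3,31.6,20.7,33.8,34.2,,
slope,-0.01,-0.01,0.32,0.11,0.31,-0.33,,
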