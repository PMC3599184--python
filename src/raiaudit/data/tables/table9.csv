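quarter,reversal_ms_ccc,reversal_ms_ltc,reversal_quad_ccc,reversal_quad_ltc,reversal_cp_ccc,reversal_cp_ltc,reversal_schiz_ccc,reversal_schiz_ltc,n_ccc,n_ltc
1996_3,5.5,,17.5,,14.9,,,,3853,
1996_4,4.2,,19.2,,16.0,,,,3600,
1997_1,9.2,,20.6,,9.4,,,,3213,
1997_2,5.0,,24.4,,8.6,,,,3184,
1997_3,6.4,,21.0,,14.7,,,,3331,
1997_4,5.0,,19.8,,23.0,,,,3329,
1998_2,4.9,,18.2,,17.2,,,,3292,
1998_3,5.1,,13.0,,9.5,,,,3290,
1998_4,8.2,,21.7,,19.1,,,,3259,
1999_1,3.1,,17.1,,19.4,,,,3131,
1999_2,4.0,,12.2,,8.2,,,,3172,
1999_3,5.6,,13.3,,13.6,,,,3242,
1999_4,6.5,,20.9,,16.9,,,,3138,
2000_1,7.5,,18.1,,11.7,,,,3104,
2000_2,4.5,,17.5,,17.7,,,,3080,
2000_3,4.0,,18.5,,15.2,,,,3133,
2000_4,6.3,,15.6,,15.4,,,,2961,
2001_1,3.7,,16.1,,11.1,,,,2915,
2001_2,5.1,,11.3,,11.6,,,,2965,
2001_3,4.2,,12.3,,9.5,,,,3059,
2001_4,5.5,,19.1,,10.3,,,,3103,
2002_1,6.0,,13.9,,3.8,,,,3168,
2002_2,3.5,,10.7,,10.3,,,,3030,
2002_3,4.4,,14.9,,14.5,,,,3041,
2002_4,5.5,,13.3,,15.2,,,,3042,
2003_1,5.8,,8.4,,14.7,,,,2931,
2003_2,3.3,,19.7,,11.3,,38.1,,2808,
2003_3,4.2,,9.0,,13.3,,16.7,,2726,
2003_4,2.5,,10.9,,11.1,,10.3,,2720,
2004_1,2.4,,12.3,,16.4,,7.2,,2715,
2004_2,1.5,,8.9,,4.7,,5.4,,2722,
2004_3,0.5,,11.7,,4.8,,2.9,,2738,
2004_4,2.1,,4.4,,9.1,,1.4,,2657,
2005_1,0.0,,7.0,,1.8,,6.8,,2631,
2005_2,1.1,,7.7,,8.3,,10.8,,2552,
2005_3,1.1,,6.3,,3.6,,7.0,,2503,
2005_4,2.4,33.3,5.3,0.0,5.6,16.7,11.5,22.2,2500,880
2006_1,0.6,0.0,4.0,0.0,7.8,11.1,3.6,4.3,2461,1941
2006_2,2.6,0.0,2.2,20.0,7.1,5.9,5.8,8.0,2478,1960
2006_3,2.5,5.0,8.5,5.6,5.3,5.7,3.9,4.2,2541,4209
2006_4,1.8,4.1,5.1,0.0,0.0,5.6,3.2,4.1,2516,9708
2007_1,1.8,1.0,4.9,2.1,13.3,5.3,3.6,1.8,2480,9699
2007_2,0.0,0.9,2.9,7.3,0.0,4.4,0.0,3.0,2457,9732
2007_3,2.7,4.3,4.2,6.0,2.1,4.1,4.7,4.2,2483,10262
2007_4,0.7,2.5,3.9,16.1,0.0,11.1,3.1,1.7,2500,12887
2008_1,1.4,1.7,3.9,5.5,0.0,6.1,8.8,4.2,2479,15044
2008_2,1.5,3.4,5.0,7.3,6.4,5.3,3.1,2.3,2404,15056
2008_3,2.1,2.1,1.8,3.3,4.3,3.6,1.4,3.0,2469,19116
2008_4,0.0,5.5,4.5,6.3,0.0,4.3,5.7,3.6,2424,20291
2009_1,1.4,1.6,2.8,10.2,2.2,1.8,3.1,4.2,2394,20075
2009_2,1.5,1.2,5.0,18.0,2.3,4.3,6.8,3.5,2302,19721
2009_3,0.0,1.6,3.3,8.1,7.3,3.8,5.3,2.5,2282,26965
2009_4,2.5,3.3,5.4,16.0,2.6,4.0,4.5,3.0,2288,42271
2010_1,3.4,1.6,3.9,20.1,7.0,4.5,7.6,3.1,2237,51059
2010_2,2.6,1.6,5.1,13.8,2.6,5.6,6.0,3.0,2250,52614
2010_3,3.9,1.4,7.6,10.3,4.9,3.6,3.1,2.8,2243,52750
2010_4,1.0,1.8,6.6,6.8,5.6,3.6,7.7,2.8,2105,52064
2011_1,0.0,2.2,3.5,7.8,0.0,2.7,6.5,2.2,2021,51771
intercept,6.3,8.0,20.6,3.9,16.8,9.3,11.7,7.9,,
slope,-0.10,-0.38,-0.33,0.41,-0.26,-0.32,-0.28,-0.31,,
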