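quarter,mood_err_ccc,mood_err_ltc,adl_dnoc_err_ccc,adl_dnoc_err_ltc,nutrition_err_ccc,nutrition_err_ltc,ulcer_err_ccc,ulcer_err_ltc,n_ccc,n_ltc
1996_3,1.1,,2.3,,0.1,,1.2,,9164,
1996_4,1.2,,2.1,,0.9,,1.0,,8604,
1997_1,0.9,,1.7,,1.0,,1.1,,8372,
1997_2,0.8,,2.0,,1.6,,1.1,,7776,
1997_3,1.0,,1.5,,0.9,,1.3,,8199,
1997_4,1.3,,1.2,,0.9,,1.3,,8067,
1998_1,1.0,,1.2,,1.0,,1.4,,8103,
1998_2,0.9,,1.5,,1.0,,1.6,,7913,
1998_3,1.0,,1.5,,1.0,,2.5,,7855,
1998_4,0.8,,1.3,,0.9,,2.8,,8024,
1999_1,0.8,,1.3,,0.8,,2.8,,7977,
1999_2,0.8,,1.5,,1.1,,2.9,,7887,
1999_3,0.7,,1.5,,0.9,,2.7,,7798,
1999_4,0.8,,1.4,,1.0,,2.8,,7883,
2000_1,0.7,,1.2,,1.1,,2.8,,7899,
2000_2,0.7,,1.3,,0.1,,3.1,,7840,
2000_3,0.7,,1.3,,0.3,,2.9,,7795,
2000_4,0.9,,1.1,,0.1,,2.7,,7607,
2001_1,0.8,,1.0,,0.1,,2.5,,7908,
2001_2,0.7,,1.0,,0.1,,2.2,,7903,
2001_3,0.7,,0.8,,0.0,,2.0,,7850,
2001_4,0.7,,0.9,,0.1,,2.0,,8020,
2002_1,0.6,,0.7,,0.1,,2.2,,7909,
2002_2,0.6,,0.6,,0.1,,2.3,,7640,
2002_3,0.6,,0.6,,0.1,,2.3,,7718,
2002_4,0.4,,0.7,,0.0,,2.1,,7732,
2003_1,0.5,,0.6,,0.1,,2.2,,7572,
2003_2,0.3,,0.2,,0.0,,0.9,,7431,
2003_3,0.0,,0.0,,0.0,,0.1,,7535,
2003_4,0.0,,0.0,,0.0,,0.0,,7748,
2004_1,0.0,,0.0,,0.0,,0.0,,7724,
2004_2,0.0,,0.0,,0.0,,0.0,,7662,
2004_3,0.0,,0.0,,0.0,,0.0,,7745,
2004_4,0.0,,0.0,,0.0,,0.0,,7718,
2005_1,0.0,,0.0,,0.0,,0.0,,7792,
2005_2,0.0,,0.0,,0.0,,0.0,,7612,
2005_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7438,1373
2005_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7519,2699
2006_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7476,2906
2006_2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7435,5825
2006_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7164,13428
2006_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7149,13589
2007_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7241,13538
2007_2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7190,14337
2007_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7077,18231
2007_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7231,21999
2008_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7137,22307
2008_2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7097,28323
2008_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6898,30750
2008_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7038,31373
2009_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6928,31305
2009_2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7124,40454
2009_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6947,61281
2009_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7192,74405
2010_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7026,77427
2010_2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6954,77554
2010_3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6979,78103
2010_4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7032,78497
2011_1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,6943,78255
intercept,1.1,0.0,1.7,0.0,0.8,0.0,2.5,0.0,,
slope,-0.02,0.00,-0.04,0.00,-0.02,0.00,-0.05,0.00,,
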