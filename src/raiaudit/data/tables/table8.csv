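quarter,height_err_ccc,height_err_ltc,weight_err_ccc,weight_err_ltc,age_err_ccc,age_err_ltc,n_ccc,n_ltc
1996_3,2.1,,9.3,,0.0,,9164,
1996_4,1.8,,11.7,,0.2,,8604,
1997_1,2.4,,13.3,,0.2,,8372,
1997_2,2.7,,16.0,,0.3,,7776,
1997_3,2.4,,19.4,,0.3,,8199,
1997_4,2.4,,20.6,,0.2,,8067,
1998_1,2.3,,20.5,,0.2,,8103,
1998_2,2.5,,20.7,,0.3,,7913,
1998_3,2.5,,19.5,,0.3,,7855,
1998_4,2.7,,18.9,,0.3,,8024,
1999_1,3.1,,16.0,,0.2,,7977,
1999_2,3.0,,17.0,,0.3,,7887,
1999_3,3.1,,15.8,,0.3,,7798,
1999_4,3.5,,13.1,,0.2,,7883,
2000_1,3.6,,12.4,,0.2,,7899,
2000_2,3.8,,10.4,,0.2,,7840,
2000_3,3.6,,10.1,,0.2,,7795,
2000_4,3.9,,11.2,,0.2,,7607,
2001_1,4.3,,11.1,,0.2,,7908,
2001_2,4.6,,10.9,,0.2,,7903,
2001_3,4.9,,10.1,,0.2,,7850,
2001_4,4.3,,10.0,,0.2,,8020,
2002_1,3.5,,10.6,,0.3,,7909,
2002_2,3.2,,12.0,,0.3,,7640,
2002_3,3.6,,11.9,,0.3,,7718,
2002_4,3.8,,11.4,,0.3,,7732,
2003_1,4.2,,10.7,,0.3,,7572,
2003_2,4.4,,5.4,,0.3,,7431,
2003_3,4.8,,5.0,,0.4,,7535,
2003_4,3.6,,4.5,,0.3,,7748,
2004_1,3.7,,3.5,,0.3,,7724,
2004_2,3.4,,3.1,,0.3,,7662,
2004_3,3.4,,3.6,,0.4,,7745,
2004_4,3.1,,3.4,,0.3,,7718,
2005_1,2.8,,3.4,,0.3,,7792,
2005_2,3.5,,3.6,,0.3,,7612,
2005_3,3.7,0.3,3.9,0.1,0.3,0.0,7438,1373
2005_4,3.7,0.5,4.0,0.1,0.5,0.0,7519,2699
2006_1,4.1,0.5,4.1,0.1,0.4,0.0,7476,2906
2006_2,4.2,0.5,4.7,0.1,0.3,0.0,7435,5825
2006_3,5.0,0.6,4.7,0.3,0.3,0.0,7164,13428
2006_4,4.6,0.5,4.5,0.2,0.2,0.0,7149,13589
2007_1,4.5,0.5,4.3,0.2,0.3,0.0,7241,13538
2007_2,5.3,0.6,4.3,0.3,0.4,0.0,7190,14337
2007_3,5.5,0.5,4.6,0.3,0.3,0.0,7077,18231
2007_4,5.7,0.6,4.9,0.4,0.3,0.0,7231,21999
2008_1,4.8,0.6,4.5,0.2,0.3,0.0,7137,22307
2008_2,4.7,0.4,4.5,0.2,0.3,0.0,7097,28323
2008_3,4.5,0.3,4.3,0.2,0.3,0.0,6898,30750
2008_4,3.7,0.3,3.4,0.2,0.3,0.0,7038,31373
2009_1,3.9,0.3,4.0,0.3,0.3,0.0,6928,31305
2009_2,4.1,0.4,4.2,0.2,0.2,0.0,7124,40454
2009_3,4.3,0.4,3.9,0.2,0.3,0.0,6947,61281
2009_4,3.9,0.3,3.9,0.3,0.3,0.0,7192,74405
2010_1,4.5,0.3,4.4,0.3,0.2,0.0,7026,77427
2010_2,3.9,0.3,4.1,0.3,0.2,0.0,6954,77554
2010_3,4.5,0.3,4.3,0.3,0.2,0.0,6979,78103
2010_4,4.1,0.3,3.9,0.3,0.2,0.0,7032,78497
2011_1,4.1,0.3,4.1,0.3,0.2,0.0,6943,78255
intercept,2.7,0.5,16.7,0.2,0.2,0.0,,
slope,0.04,-0.01,-0.27,0.01,0.00,0.00,,
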