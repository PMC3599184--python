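quarter,therapy_day15_ccc,therapy_day15_ltc,therapy_nodays_ccc,therapy_nodays_ltc,therapy_exceed_ccc,therapy_exceed_ltc,any_therapy_ccc,any_therapy_ltc,any_logical_ccc,any_logical_ltc,n_ccc,n_ltc
1996_3,1.6,,0.1,,0.0,,1.7,,6.4,,9164,
1996_4,1.9,,0.0,,0.0,,2.0,,7.1,,8604,
1997_1,2.0,,0.0,,0.0,,2.1,,6.8,,8372,
1997_2,2.1,,0.1,,0.1,,2.3,,7.8,,7776,
1997_3,2.0,,0.1,,0.0,,2.0,,6.8,,8199,
1997_4,1.7,,0.0,,0.0,,1.8,,6.5,,8067,
1998_1,2.2,,0.0,,0.0,,2.3,,7.0,,8103,
1998_2,2.0,,0.2,,0.1,,2.2,,7.2,,7913,
1998_3,2.1,,0.1,,0.0,,2.2,,8.2,,7855,
1998_4,1.7,,0.1,,0.0,,1.8,,7.6,,8024,
1999_1,2.0,,0.1,,0.2,,2.2,,8.0,,7977,
1999_2,1.9,,0.1,,0.1,,2.0,,8.2,,7887,
1999_3,1.6,,0.1,,0.0,,1.7,,7.5,,7798,
1999_4,2.0,,0.0,,0.1,,2.1,,8.1,,7883,
2000_1,1.6,,0.1,,0.1,,1.8,,7.7,,7899,
2000_2,1.4,,0.1,,0.0,,1.5,,6.7,,7840,
2000_3,1.3,,0.0,,0.1,,1.3,,6.4,,7795,
2000_4,1.7,,0.1,,0.1,,1.9,,6.7,,7607,
2001_1,1.3,,0.0,,0.0,,1.4,,5.7,,7908,
2001_2,1.3,,0.1,,0.1,,1.5,,5.5,,7903,
2001_3,1.7,,0.1,,0.1,,1.9,,5.3,,7850,
2001_4,1.5,,0.0,,0.0,,1.6,,5.2,,8020,
2002_1,1.3,,0.1,,0.0,,1.4,,4.9,,7909,
2002_2,1.3,,0.1,,0.1,,1.5,,5.2,,7640,
2002_3,1.2,,0.1,,0.0,,1.3,,4.9,,7718,
2002_4,0.8,,0.1,,0.0,,0.9,,4.2,,7732,
2003_1,0.8,,0.0,,0.0,,0.9,,4.2,,7572,
2003_2,1.1,,0.1,,0.0,,1.3,,2.7,,7431,
2003_3,1.9,,0.0,,0.0,,1.9,,2.1,,7535,
2003_4,2.2,,0.0,,0.0,,2.2,,2.2,,7748,
2004_1,1.4,,0.0,,0.0,,1.4,,1.4,,7724,
2004_2,1.5,,0.0,,0.0,,1.5,,1.5,,7662,
2004_3,2.5,,0.0,,0.0,,2.6,,2.6,,7745,
2004_4,2.0,,0.0,,0.0,,2.0,,2.0,,7718,
2005_1,2.2,,0.0,,0.1,,2.2,,2.2,,7792,
2005_2,2.3,,0.0,,0.0,,2.3,,2.3,,7612,
2005_3,2.6,3.0,0.0,0.0,0.0,0.0,2.6,3.0,2.6,3.0,7438,1373
2005_4,2.6,1.9,0.0,0.0,0.0,0.0,2.6,1.9,2.6,1.9,7519,2699
2006_1,2.9,2.2,0.0,0.0,0.0,0.0,2.9,2.2,2.9,2.2,7476,2906
2006_2,2.5,2.5,0.0,0.0,0.1,0.0,2.6,2.5,2.6,2.5,7435,5825
2006_3,2.5,2.4,0.0,0.0,0.0,0.0,2.6,2.5,2.6,2.5,7164,13428
2006_4,2.5,2.5,0.0,0.0,0.0,0.0,2.6,2.5,2.6,2.5,7149,13589
2007_1,2.5,2.5,0.0,0.0,0.0,0.1,2.5,2.6,2.5,2.6,7241,13538
2007_2,2.3,2.8,0.0,0.0,0.0,0.0,2.3,2.8,2.3,2.8,7190,14337
2007_3,2.7,2.4,0.0,0.0,0.0,0.0,2.8,2.4,2.8,2.4,7077,18231
2007_4,2.1,2.4,0.0,0.0,0.0,0.0,2.2,2.5,2.2,2.5,7231,21999
2008_1,2.2,2.7,0.0,0.0,0.0,0.0,2.2,2.7,2.2,2.7,7137,22307
2008_2,2.5,2.7,0.0,0.0,0.0,0.0,2.5,2.7,2.5,2.7,7097,28323
2008_3,2.3,2.5,0.0,0.0,0.0,0.0,2.3,2.5,2.3,2.5,6898,30750
2008_4,2.5,2.4,0.0,0.0,0.0,0.0,2.5,2.4,2.5,2.4,7038,31373
2009_1,2.4,2.9,0.0,0.0,0.0,0.0,2.5,2.9,2.5,2.9,6928,31305
2009_2,2.8,2.6,0.0,0.0,0.0,0.0,2.8,2.6,2.8,2.6,7124,40454
2009_3,2.7,2.2,0.0,0.0,0.0,0.0,2.7,2.2,2.7,2.2,6947,61281
2009_4,2.0,1.9,0.0,0.0,0.0,0.0,2.0,1.9,2.0,1.9,7192,74405
2010_1,2.2,1.6,0.0,0.0,0.0,0.0,2.2,1.6,2.2,1.6,7026,77427
2010_2,2.1,1.5,0.0,0.0,0.0,0.0,2.1,1.5,2.1,1.5,6954,77554
2010_3,2.0,1.3,0.0,0.0,0.0,0.0,2.0,1.4,2.0,1.4,6979,78103
2010_4,2.0,1.4,0.0,0.0,0.0,0.0,2.0,1.4,2.0,1.4,7032,78497
2011_1,2.3,1.4,0.0,0.0,0.0,0.0,2.3,1.4,2.3,1.4,6943,78255
intercept,1.6,2.8,0.1,0.0,0.1,0.0,1.7,2.9,7.7,2.9,,
slope,0.01,-0.05,-0.00,0.00,-0.00,-0.00,0.01,-0.05,-0.12,-0.05,,
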