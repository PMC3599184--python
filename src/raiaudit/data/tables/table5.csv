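quarter,alpha_adl_ccc,alpha_adl_ltc,alpha_drs_ccc,alpha_drs_ltc,alpha_abs_ccc,alpha_abs_ltc,n_ccc,n_ltc
1996_3,0.91,,0.76,,0.76,,9164,
1996_4,0.91,,0.76,,0.75,,8604,
1997_1,0.91,,0.75,,0.76,,8372,
1997_2,0.92,,0.76,,0.77,,7776,
1997_3,0.91,,0.77,,0.77,,8199,
1997_4,0.92,,0.77,,0.77,,8067,
1998_1,0.91,,0.77,,0.77,,8103,
1998_2,0.92,,0.76,,0.78,,7913,
1998_3,0.92,,0.76,,0.78,,7855,
1998_4,0.92,,0.76,,0.77,,8024,
1999_1,0.92,,0.76,,0.78,,7977,
1999_2,0.92,,0.75,,0.78,,7887,
1999_3,0.92,,0.75,,0.78,,7798,
1999_4,0.92,,0.75,,0.78,,7883,
2000_1,0.92,,0.75,,0.79,,7899,
2000_2,0.92,,0.76,,0.80,,7840,
2000_3,0.92,,0.75,,0.80,,7795,
2000_4,0.92,,0.76,,0.80,,7607,
2001_1,0.92,,0.75,,0.79,,7908,
2001_2,0.92,,0.75,,0.79,,7903,
2001_3,0.92,,0.75,,0.78,,7850,
2001_4,0.92,,0.74,,0.78,,8020,
2002_1,0.92,,0.74,,0.79,,7909,
2002_2,0.92,,0.75,,0.79,,7640,
2002_3,0.92,,0.75,,0.79,,7718,
2002_4,0.92,,0.75,,0.78,,7732,
2003_1,0.92,,0.75,,0.79,,7572,
2003_2,0.92,,0.76,,0.77,,7431,
2003_3,0.92,,0.77,,0.78,,7535,
2003_4,0.92,,0.76,,0.77,,7748,
2004_1,0.92,,0.76,,0.77,,7724,
2004_2,0.92,,0.75,,0.78,,7662,
2004_3,0.92,,0.76,,0.77,,7745,
2004_4,0.92,,0.76,,0.76,,7718,
2005_1,0.92,,0.76,,0.77,,7792,
2005_2,0.92,,0.75,,0.77,,7612,
2005_3,0.92,0.92,0.75,0.72,0.78,0.79,7438,1373
2005_4,0.93,0.93,0.75,0.70,0.79,0.75,7519,2699
2006_1,0.93,0.93,0.77,0.73,0.78,0.75,7476,2906
2006_2,0.93,0.93,0.77,0.71,0.79,0.74,7435,5825
2006_3,0.93,0.93,0.76,0.71,0.80,0.73,7164,13428
2006_4,0.93,0.93,0.76,0.70,0.80,0.72,7149,13589
2007_1,0.92,0.93,0.75,0.70,0.80,0.72,7241,13538
2007_2,0.92,0.93,0.76,0.70,0.80,0.72,7190,14337
2007_3,0.92,0.94,0.76,0.70,0.80,0.72,7077,18231
2007_4,0.92,0.94,0.76,0.71,0.80,0.73,7231,21999
2008_1,0.92,0.94,0.76,0.71,0.80,0.73,7137,22307
2008_2,0.92,0.94,0.75,0.71,0.79,0.73,7097,28323
2008_3,0.92,0.94,0.76,0.71,0.80,0.73,6898,30750
2008_4,0.92,0.94,0.76,0.72,0.79,0.72,7038,31373
2009_1,0.92,0.94,0.75,0.71,0.81,0.72,6928,31305
2009_2,0.92,0.94,0.75,0.72,0.80,0.73,7124,40454
2009_3,0.92,0.94,0.75,0.72,0.80,0.73,6947,61281
2009_4,0.92,0.94,0.75,0.71,0.81,0.73,7192,74405
2010_1,0.92,0.94,0.75,0.71,0.79,0.73,7026,77427
2010_2,0.92,0.94,0.74,0.71,0.80,0.74,6954,77554
2010_3,0.92,0.94,0.75,0.71,0.80,0.74,6979,78103
2010_4,0.93,0.94,0.75,0.71,0.79,0.73,7032,78497
2011_1,0.92,0.94,0.73,0.71,0.79,0.73,6943,78255
intercept,0.92,0.93,0.76,0.71,0.77,0.74,,
slope,0.00,0.00,0.00,0.00,0.00,-0.00,,
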