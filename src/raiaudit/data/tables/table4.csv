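quarter,bowel_cps3_v_ccc,bowel_cps3_v_ltc,adl_cps_r_ccc,adl_cps_r_ltc,pain_cps_r_ccc,pain_cps_r_ltc,abs_cps_r_ccc,abs_cps_r_ltc,n_ccc,n_ltc
1996_3,0.42,,0.59,,-0.25,,0.28,,9164,
1996_4,0.41,,0.58,,-0.23,,0.30,,8604,
1997_1,0.43,,0.59,,-0.22,,0.30,,8372,
1997_2,0.43,,0.58,,-0.20,,0.31,,7776,
1997_3,0.43,,0.57,,-0.23,,0.30,,8199,
1997_4,0.44,,0.58,,-0.22,,0.30,,8067,
1998_1,0.43,,0.58,,-0.21,,0.31,,8103,
1998_2,0.45,,0.59,,-0.21,,0.30,,7913,
1998_3,0.43,,0.59,,-0.19,,0.30,,7855,
1998_4,0.45,,0.58,,-0.21,,0.30,,8024,
1999_1,0.46,,0.59,,-0.21,,0.29,,7977,
1999_2,0.46,,0.58,,-0.21,,0.29,,7887,
1999_3,0.45,,0.58,,-0.20,,0.30,,7798,
1999_4,0.45,,0.57,,-0.20,,0.30,,7883,
2000_1,0.44,,0.57,,-0.17,,0.29,,7899,
2000_2,0.44,,0.57,,-0.20,,0.31,,7840,
2000_3,0.46,,0.57,,-0.20,,0.30,,7795,
2000_4,0.44,,0.58,,-0.18,,0.30,,7607,
2001_1,0.44,,0.57,,-0.19,,0.30,,7908,
2001_2,0.43,,0.57,,-0.19,,0.30,,7903,
2001_3,0.42,,0.57,,-0.17,,0.31,,7850,
2001_4,0.44,,0.57,,-0.16,,0.33,,8020,
2002_1,0.44,,0.57,,-0.17,,0.33,,7909,
2002_2,0.44,,0.58,,-0.17,,0.33,,7640,
2002_3,0.42,,0.57,,-0.17,,0.33,,7718,
2002_4,0.41,,0.56,,-0.17,,0.32,,7732,
2003_1,0.40,,0.55,,-0.19,,0.31,,7572,
2003_2,0.41,,0.56,,-0.20,,0.32,,7431,
2003_3,0.43,,0.57,,-0.19,,0.33,,7535,
2003_4,0.42,,0.56,,-0.18,,0.32,,7748,
2004_1,0.40,,0.56,,-0.18,,0.32,,7724,
2004_2,0.42,,0.56,,-0.18,,0.32,,7662,
2004_3,0.42,,0.55,,-0.19,,0.33,,7745,
2004_4,0.39,,0.55,,-0.19,,0.32,,7718,
2005_1,0.42,,0.55,,-0.19,,0.32,,7792,
2005_2,0.42,,0.55,,-0.17,,0.31,,7612,
2005_3,0.42,0.45,0.53,0.59,-0.20,-0.22,0.32,0.40,7438,1373
2005_4,0.41,0.41,0.53,0.59,-0.19,-0.22,0.31,0.43,7519,2699
2006_1,0.41,0.45,0.56,0.61,-0.18,-0.20,0.31,0.43,7476,2906
2006_2,0.43,0.43,0.55,0.60,-0.17,-0.18,0.33,0.39,7435,5825
2006_3,0.41,0.38,0.56,0.56,-0.18,-0.16,0.34,0.36,7164,13428
2006_4,0.40,0.41,0.54,0.57,-0.19,-0.17,0.34,0.36,7149,13589
2007_1,0.39,0.42,0.52,0.57,-0.19,-0.18,0.34,0.37,7241,13538
2007_2,0.39,0.41,0.50,0.57,-0.20,-0.18,0.35,0.37,7190,14337
2007_3,0.38,0.42,0.51,0.57,-0.18,-0.17,0.35,0.35,7077,18231
2007_4,0.37,0.43,0.51,0.57,-0.18,-0.16,0.33,0.35,7231,21999
2008_1,0.38,0.43,0.50,0.58,-0.19,-0.18,0.33,0.35,7137,22307
2008_2,0.37,0.43,0.51,0.57,-0.19,-0.18,0.34,0.35,7097,28323
2008_3,0.37,0.42,0.50,0.58,-0.18,-0.17,0.33,0.34,6898,30750
2008_4,0.36,0.43,0.50,0.58,-0.21,-0.18,0.35,0.35,7038,31373
2009_1,0.36,0.42,0.49,0.58,-0.16,-0.17,0.33,0.34,6928,31305
2009_2,0.36,0.41,0.49,0.58,-0.18,-0.16,0.35,0.34,7124,40454
2009_3,0.34,0.40,0.49,0.57,-0.18,-0.15,0.35,0.34,6947,61281
2009_4,0.36,0.40,0.49,0.57,-0.20,-0.15,0.34,0.33,7192,74405
2010_1,0.36,0.40,0.49,0.57,-0.18,-0.16,0.35,0.34,7026,77427
2010_2,0.37,0.40,0.49,0.57,-0.17,-0.15,0.34,0.34,6954,77554
2010_3,0.39,0.41,0.51,0.57,-0.18,-0.16,0.34,0.34,6979,78103
2010_4,0.37,0.40,0.52,0.57,-0.17,-0.16,0.34,0.33,7032,78497
2011_1,0.37,0.40,0.53,0.56,-0.19,-0.16,0.33,0.33,6943,78255
intercept,0.46,0.43,0.60,0.59,0.21,0.20,0.29,0.40,,
slope,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,,
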