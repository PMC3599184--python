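quarter,admission_ccc,admission_ltc,cps3_ccc,cps3_ltc,rugadl11_ccc,rugadl11_ltc,abs5_ccc,abs5_ltc,drs3_ccc,drs3_ltc,n_ccc,n_ltc
1996_3,32.9,,64.2,,75.0,,11.5,,24.6,,9164,
1996_4,28.7,,64.0,,75.1,,10.6,,23.6,,8604,
1997_1,30.1,,63.4,,74.5,,10.7,,22.8,,8372,
1997_2,33.2,,62.7,,73.4,,10.6,,22.7,,7776,
1997_3,30.9,,63.4,,74.5,,10.6,,22.5,,8199,
1997_4,32.6,,62.7,,74.1,,10.4,,22.8,,8067,
1998_1,34.4,,61.5,,73.5,,9.8,,23.1,,8103,
1998_2,34.8,,61.5,,73.3,,10.2,,22.5,,7913,
1998_3,33.8,,61.6,,73.3,,9.5,,22.6,,7855,
1998_4,36.3,,61.1,,73.1,,9.4,,22.4,,8024,
1999_1,37.8,,60.4,,72.1,,9.3,,22.1,,7977,
1999_2,36.0,,60.0,,72.0,,9.4,,22.5,,7887,
1999_3,35.4,,60.3,,72.7,,9.0,,22.6,,7798,
1999_4,37.0,,60.1,,73.0,,8.9,,23.3,,7883,
2000_1,37.9,,60.8,,73.2,,9.2,,24.2,,7899,
2000_2,39.0,,60.1,,72.9,,9.0,,24.7,,7840,
2000_3,37.9,,59.4,,72.4,,9.1,,24.3,,7795,
2000_4,41.1,,58.7,,72.2,,8.5,,24.5,,7607,
2001_1,42.8,,58.8,,72.5,,8.3,,24.0,,7908,
2001_2,42.7,,59.1,,73.4,,8.4,,24.6,,7903,
2001_3,41.9,,59.4,,74.0,,9.0,,26.5,,7850,
2001_4,43.0,,58.3,,73.6,,9.3,,26.7,,8020,
2002_1,42.7,,59.0,,73.5,,9.8,,27.0,,7909,
2002_2,43.5,,58.4,,73.5,,8.7,,26.4,,7640,
2002_3,44.5,,57.8,,73.6,,8.3,,26.8,,7718,
2002_4,45.3,,57.6,,72.1,,7.8,,26.8,,7732,
2003_1,45.2,,58.4,,73.0,,7.7,,27.4,,7572,
2003_2,49.3,,57.8,,71.5,,7.8,,26.2,,7431,
2003_3,49.8,,55.9,,71.1,,7.5,,26.5,,7535,
2003_4,47.4,,54.4,,71.0,,6.9,,26.3,,7748,
2004_1,48.3,,54.3,,70.7,,6.9,,25.7,,7724,
2004_2,48.0,,54.2,,70.6,,6.7,,26.0,,7662,
2004_3,49.0,,53.2,,69.9,,6.9,,24.5,,7745,
2004_4,49.7,,53.7,,69.5,,6.6,,24.3,,7718,
2005_1,51.4,,52.2,,69.6,,6.5,,24.6,,7792,
2005_2,50.9,,53.3,,68.9,,6.5,,25.2,,7612,
2005_3,50.8,6.8,52.9,64.2,70.6,62.4,6.8,19.3,26.1,31.6,7438,1373
2005_4,51.9,8.4,52.4,62.7,70.0,57.3,6.6,18.4,24.2,33.6,7519,2699
2006_1,52.1,9.3,52.1,61.9,69.6,56.6,6.6,16.5,25.0,34.1,7476,2906
2006_2,48.0,21.3,51.3,60.9,70.1,57.4,7.0,15.2,26.5,35.0,7435,5825
2006_3,45.8,22.4,52.6,61.2,71.3,59.0,7.1,14.4,26.6,35.2,7164,13428
2006_4,46.6,8.5,52.3,62.0,70.4,60.2,7.5,14.1,26.5,36.0,7149,13589
2007_1,49.1,9.7,51.9,60.8,71.3,60.0,7.2,13.9,27.2,35.1,7241,13538
2007_2,49.6,9.0,51.3,60.0,71.6,58.9,7.4,13.3,27.9,34.1,7190,14337
2007_3,47.8,8.7,51.0,59.1,70.4,58.9,7.7,12.2,27.5,32.5,7077,18231
2007_4,49.3,8.9,49.7,58.7,71.2,57.7,7.4,12.1,26.4,32.4,7231,21999
2008_1,48.2,9.4,50.9,58.1,70.8,56.8,7.7,11.6,26.8,31.6,7137,22307
2008_2,50.0,8.9,50.5,58.1,71.7,57.1,7.0,11.8,24.9,30.8,7097,28323
2008_3,47.2,7.8,50.6,58.5,72.1,57.4,7.1,11.3,25.5,30.1,6898,30750
2008_4,49.5,8.5,49.2,58.0,72.2,57.4,6.6,11.0,24.7,29.0,7038,31373
2009_1,50.0,8.7,50.0,57.3,71.9,57.1,6.7,10.5,24.9,27.7,6928,31305
2009_2,53.4,8.5,49.5,57.9,70.4,57.9,6.7,11.1,24.3,29.6,7124,40454
2009_3,51.4,7.4,50.4,58.3,71.3,58.5,6.9,11.8,24.2,32.7,6947,61281
2009_4,51.9,8.1,49.5,58.0,71.0,59.2,6.4,12.0,23.1,33.4,7192,74405
2010_1,50.7,8.8,48.3,57.7,70.2,59.8,6.3,12.0,22.8,32.9,7026,77427
2010_2,51.9,8.6,47.0,57.5,70.3,60.0,5.8,11.5,22.7,32.2,6954,77554
2010_3,52.2,8.1,47.4,57.8,70.2,60.6,6.1,11.3,23.2,31.4,6979,78103
2010_4,54.9,9.0,45.4,58.0,68.9,60.9,5.7,11.2,22.6,31.5,7032,78497
2011_1,56.6,9.3,47.0,58.3,70.3,61.6,5.6,11.2,23.1,31.8,6943,78255
intercept,32.8,12.0,64.4,62.3,74.0,58.0,10.3,16.4,23.9,34.1,,
slope,0.39,-0.19,-0.30,-0.25,-0.07,0.07,-0.08,-0.29,0.03,-0.15,,
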