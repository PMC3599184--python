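quarter,therapy_minutes_ccc,therapy_minutes_ltc,nursing_rehab_2plus_ccc,nursing_rehab_2plus_ltc,any_ot_ccc,any_ot_ltc,any_pt_ccc,any_pt_ltc,rehab_3d45m_ccc,rehab_3d45m_ltc,rehab_5d150m_ccc,rehab_5d150m_ltc,n_ccc,n_ltc
1996_3,66.0,,26.8,,23.9,,37.4,,29.7,,12.8,,9164,
1996_4,64.3,,28.2,,23.7,,38.1,,29.8,,12.5,,8604,
1997_1,65.6,,28.5,,23.1,,38.3,,30.2,,13.0,,8372,
1997_2,75.8,,29.5,,25.7,,39.6,,32.5,,15.0,,7776,
1997_3,72.2,,29.6,,26.4,,41.2,,33.5,,15.0,,8199,
1997_4,75.2,,32.8,,29.2,,41.6,,34.8,,15.3,,8067,
1998_1,80.7,,33.5,,31.2,,44.3,,36.7,,16.6,,8103,
1998_2,81.8,,35.1,,31.1,,44.9,,36.9,,16.7,,7913,
1998_3,80.8,,34.5,,29.1,,44.7,,36.4,,16.4,,7855,
1998_4,80.2,,33.9,,29.0,,45.5,,36.8,,16.7,,8024,
1999_1,89.8,,35.6,,30.3,,46.3,,37.1,,16.5,,7977,
1999_2,80.2,,35.2,,30.3,,46.6,,36.2,,16.0,,7887,
1999_3,80.0,,35.3,,31.2,,47.3,,37.4,,17.0,,7798,
1999_4,82.2,,37.3,,32.1,,47.9,,38.3,,16.7,,7883,
2000_1,86.2,,39.2,,35.3,,48.4,,39.9,,18.4,,7899,
2000_2,84.0,,39.6,,34.5,,50.0,,40.6,,18.4,,7840,
2000_3,87.2,,40.3,,33.2,,47.5,,38.9,,17.5,,7795,
2000_4,87.6,,41.9,,34.5,,49.2,,40.0,,17.8,,7607,
2001_1,85.2,,42.3,,35.9,,49.2,,40.5,,18.1,,7908,
2001_2,88.0,,49.3,,36.6,,48.8,,40.8,,18.0,,7903,
2001_3,85.4,,53.8,,35.4,,49.3,,40.4,,17.7,,7850,
2001_4,85.7,,57.8,,35.9,,51.7,,42.2,,18.5,,8020,
2002_1,88.6,,61.4,,36.6,,53.4,,44.1,,19.3,,7909,
2002_2,98.8,,64.4,,38.5,,53.8,,45.1,,20.3,,7640,
2002_3,96.4,,63.9,,36.7,,53.2,,44.1,,20.7,,7718,
2002_4,96.9,,64.7,,39.6,,55.2,,45.9,,20.6,,7732,
2003_1,97.3,,65.7,,40.0,,55.5,,45.6,,21.0,,7572,
2003_2,100.2,,65.9,,40.6,,55.7,,46.4,,21.6,,7431,
2003_3,95.8,,65.2,,39.7,,56.2,,46.1,,20.5,,7535,
2003_4,98.9,,64.9,,42.5,,56.8,,47.8,,22.1,,7748,
2004_1,106.4,,64.9,,43.4,,58.9,,50.3,,24.1,,7724,
2004_2,108.6,,65.2,,44.8,,60.6,,51.3,,24.6,,7662,
2004_3,110.3,,66.0,,45.3,,59.7,,51.0,,25.3,,7745,
2004_4,110.7,,64.1,,46.3,,60.9,,51.2,,25.3,,7718,
2005_1,112.1,,65.7,,46.3,,60.7,,51.6,,25.9,,7792,
2005_2,117.8,,66.7,,48.2,,62.7,,53.3,,27.5,,7612,
2005_3,118.8,14.8,66.9,23.1,51.8,2.3,63.6,32.1,54.7,13.0,28.4,0.2,7438,1373
2005_4,116.1,10.3,66.2,14.1,52.4,1.4,62.9,23.3,54.4,9.9,27.4,0.3,7519,2699
2006_1,119.4,10.2,66.3,12.9,53.1,1.5,64.5,21.9,55.5,8.9,28.9,0.3,7476,2906
2006_2,121.6,19.2,68.5,9.4,53.5,3.2,64.6,35.5,55.7,16.5,28.5,0.4,7435,5825
2006_3,117.2,22.9,67.9,8.3,50.8,2.6,63.7,41.7,53.7,19.3,27.8,0.5,7164,13428
2006_4,119.0,22.7,68.6,9.3,52.9,3.2,63.9,43.7,54.7,17.4,28.2,0.6,7149,13589
2007_1,114.7,24.7,67.9,11.5,51.2,2.9,63.3,45.6,53.8,17.0,27.0,0.4,7241,13538
2007_2,120.1,24.6,68.4,14.6,52.7,3.1,65.0,47.8,55.5,18.8,28.3,0.6,7190,14337
2007_3,118.6,25.2,69.9,15.1,52.6,2.5,64.0,49.1,55.1,19.5,27.9,0.8,7077,18231
2007_4,121.4,25.2,69.1,15.5,53.6,2.0,65.2,49.6,55.9,19.9,29.4,0.8,7231,21999
2008_1,119.5,25.0,69.0,15.0,54.2,2.0,65.0,49.2,56.6,20.9,29.5,0.9,7137,22307
2008_2,122.4,26.0,68.6,13.9,53.5,2.4,66.2,50.5,57.4,22.6,30.8,0.9,7097,28323
2008_3,117.4,27.3,69.2,13.5,53.8,3.0,65.9,54.3,56.9,24.5,28.7,0.8,6898,30750
2008_4,124.6,27.6,67.2,13.9,56.2,3.3,68.2,55.2,59.1,25.6,31.5,1.1,7038,31373
2009_1,127.2,28.5,66.9,14.6,56.6,3.3,68.2,57.4,59.5,27.8,32.5,1.2,6928,31305
2009_2,128.5,31.3,68.1,13.8,57.1,3.0,68.6,61.6,60.0,31.1,32.0,1.1,7124,40454
2009_3,122.2,33.3,69.6,13.3,55.1,2.8,67.3,64.9,58.6,35.8,30.9,1.2,6947,61281
2009_4,123.2,35.6,69.0,16.4,54.4,2.8,66.9,68.7,58.6,41.8,30.0,1.3,7192,74405
2010_1,127.9,38.1,68.8,22.2,55.9,3.5,69.1,73.1,60.6,49.4,31.5,1.2,7026,77427
2010_2,133.4,40.6,67.6,25.6,57.5,3.7,69.6,77.5,61.8,56.7,32.4,1.3,6954,77554
2010_3,130.7,41.0,68.3,27.7,56.6,3.4,69.9,79.2,61.3,59.1,31.5,1.2,6979,78103
2010_4,137.6,41.8,67.4,28.2,57.1,3.5,71.1,80.1,61.9,61.9,33.9,1.2,7032,78497
2011_1,142.0,42.4,64.3,26.7,58.5,3.3,71.5,81.1,63.2,63.2,34.8,1.3,6943,78255
intercept,67.5,11.9,32.0,9.5,23.9,2.1,39.4,24.2,30.8,1.3,12.3,0.2,,
slope,1.17,1.32,0.79,0.58,0.63,0.06,0.57,2.49,0.56,2.36,0.37,0.05,,
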