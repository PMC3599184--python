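quarter,neg_ccc,neg_ltc,d0_6_ccc,d0_6_ltc,d7_30_ccc,d7_30_ltc,gt30_ccc,gt30_ltc
1996,4.0,,55.6,,16.3,,24.1,
1997,4.0,,65.2,,16.5,,14.3,
1998,3.0,,71.3,,15.9,,9.8,
1999,2.9,,72.0,,14.4,,10.7,
2000,3.0,,68.1,,16.0,,13.0,
2001,2.6,,70.6,,15.6,,11.2,
2002,2.5,,68.3,,19.1,,10.1,
2003,3.7,,66.1,,18.2,,12.1,
2004,1.0,,69.1,,19.9,,10.1,
2005,0.0,0,70.6,46.13,20.3,34.42,9.1,19.46
2006,0.0,0,67.2,46.9,22.3,42.79,10.6,10.31
2007,0.0,0,64.8,52.99,24.4,41.99,10.8,5.02
2008,0.0,0,65.6,50.8,24.0,43.72,10.3,5.47
2009,0.0,0,64.7,48.95,25.3,45.79,10.1,5.26
2010,0.0,0,62.7,53.73,26.2,43.39,11.2,2.88
2011,0.0,0,60.7,52.68,29.5,44.67,9.8,2.65
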