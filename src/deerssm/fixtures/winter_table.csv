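year,carcasses,distance_km,sd50_days,maxs_cm
2008,30,78.5,52,132
2009,0,85.0,40,130
2010,0,98.5,0,36.7
2011,25,88.5,76,141.7
2012,4,83.5,87,138.3
2013,7,101.5,21,90.7
2014,6,83.5,70,114
2015,38,100.0,71,113
2016,2,92.5,0,31
2017,30,86.5,61,135
2018,0,93.0,7,87
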