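year,season,harvest,effort
2007,MAY_JUN,0,0
2007,JUL_AUG,0,0
2007,SEP_OCT,0,0
2007,NOV_DEC,0,0
2008,MAY_JUN,0,0
2008,JUL_AUG,0,0
2008,SEP_OCT,0,6
2008,NOV_DEC,10,24
2009,MAY_JUN,0,6
2009,JUL_AUG,0,0
2009,SEP_OCT,0,6
2009,NOV_DEC,3,20
2010,MAY_JUN,0,0
2010,JUL_AUG,0,0
2010,SEP_OCT,0,0
2010,NOV_DEC,7,6
2011,MAY_JUN,0,0
2011,JUL_AUG,0,0
2011,SEP_OCT,4,8
2011,NOV_DEC,1,8
2012,MAY_JUN,0,0
2012,JUL_AUG,0,0
2012,SEP_OCT,5,13
2012,NOV_DEC,3,6
2013,MAY_JUN,15,25
2013,JUL_AUG,0,0
2013,SEP_OCT,3,14
2013,NOV_DEC,4,11
2014,MAY_JUN,17,12
2014,JUL_AUG,1,2
2014,SEP_OCT,4,8
2014,NOV_DEC,10,4
2015,MAY_JUN,6,14
2015,JUL_AUG,2,4
2015,SEP_OCT,2,19
2015,NOV_DEC,2,6
2016,MAY_JUN,8,19
2016,JUL_AUG,2,6
2016,SEP_OCT,2,10
2016,NOV_DEC,5,16
2017,MAY_JUN,1,14
2017,JUL_AUG,0,0
2017,SEP_OCT,0,0
2017,NOV_DEC,4,20
2018,MAY_JUN,4,4
2018,JUL_AUG,0,0
2018,SEP_OCT,2,20
2018,NOV_DEC,0,0
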