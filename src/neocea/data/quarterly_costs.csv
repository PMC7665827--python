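period_start,period_end,operational,infrastructure
2012-05,2012-07,49507,0
2012-09,2012-11,19340,0
2013-01,2013-03,75876,0
2013-05,2013-07,38717,300
2013-09,2013-11,97617,0
2013-12,2014-02,153784,42960
2014-03,2014-05,156542,3000
2014-06,2014-08,58431,0
2014-09,2014-11,112782,0
2014-12,2015-02,148858,82918
2015-03,2015-05,167297,3125
2015-06,2015-08,186313,0
2015-09,2015-11,83959,2500
2015-12,2016-02,104373,2077
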