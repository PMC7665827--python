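year,deliveries,neonatal_deaths,stillbirths
2012,11338,353,135
2013,7549,179,77
2014,9672,165,96
2015,8807,208,83
2016,8129,204,67
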