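site,chla_ef,dbt_ef,dbt_post2000_ng_g,breakpoint_excluded,exclusion_reason
RAMP 271,1.9,0.7,80.4,False,
2014-Y,1.6,1.1,21.1,False,
Big Peter Pond,2.3,1.5,21.4,True,outlier-driven breakpoint
2014-D,2.1,1.6,29.8,False,
Laloche,1.4,1.8,34.2,False,
RAMP 464,1.3,1.9,49.7,False,
NE13,5.3,2.1,176.4,False,
RAMP 226,1.3,2.3,117.9,True,no stable baseline
2014-X,1.3,2.4,26.5,False,
2014-Z,1.5,2.6,28.3,False,
RAMP 225,2.6,2.7,124.3,False,
Gregoire,1.3,2.7,92.5,False,
RAMP 175,2.2,2.9,62.7,True,no stable baseline
Kearl,1.3,3.1,388.2,False,
SE22,1.2,3.9,213.2,False,
RAMP 223,1.3,5.1,147.9,False,
RAMP 209,1.3,6.2,162.2,False,
RAMP 268,1.7,7.1,324.9,False,
2014-B,2.0,7.5,290.8,True,no stable baseline
RAMP 185,1.5,8.6,231.0,False,
NE20,1.7,22.8,1235.0,False,
Pushup,1.3,37.4,101.9,False,
RAMP 227,1.1,,,True,no pre-industrial DBT record
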