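compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard
5,dpph,ec50,12.5,11.0,14.0,uM,ok,False
7,dpph,ec50,19.5,18.0,21.0,uM,ok,False
9,dpph,ec50,20.0,18.0,22.0,uM,ok,False
10,dpph,ec50,20.5,18.0,23.0,uM,ok,False
11,dpph,ec50,19.5,16.0,23.0,uM,ok,False
12,dpph,ec50,22.0,19.0,25.0,uM,ok,False
13,dpph,ec50,15.5,15.0,16.0,uM,ok,False
18,dpph,ec50,25.0,23.0,27.0,uM,ok,False
19,dpph,ec50,31.0,27.0,35.0,uM,ok,False
21,dpph,ec50,21.5,20.0,23.0,uM,ok,False
ascorbic_acid,dpph,ec50,22.0,21.0,23.0,uM,ok,True
gallic_acid,dpph,ec50,5.5,5.0,6.0,uM,ok,True
quercetin,dpph,ec50,4.5,4.0,5.0,uM,ok,True
scopoletin,dpph,ec50,125.0,110.0,140.0,uM,ok,True
aesculin,dpph,ec50,2250.0,1100.0,3400.0,uM,ok,True
trolox,dpph,ec50,16.0,14.0,18.0,uM,ok,True
curcumin,dpph,ec50,13.0,12.0,14.0,uM,ok,True
resveratrol,dpph,ec50,15.5,13.0,18.0,uM,ok,True
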