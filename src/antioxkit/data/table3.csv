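compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard
5,dr2,ic50,73.5,70.0,77.0,uM,ok,False
7,dr2,ic50,11.0,10.0,12.0,uM,ok,False
9,dr2,ic50,45.0,43.0,47.0,uM,ok,False
10,dr2,ic50,,,,uM,insoluble,False
11,dr2,ic50,41.5,40.0,43.0,uM,ok,False
12,dr2,ic50,49.5,48.0,51.0,uM,ok,False
13,dr2,ic50,36.0,35.0,37.0,uM,ok,False
18,dr2,ic50,93.5,84.0,103.0,uM,ok,False
19,dr2,ic50,,,,uM,pro_oxidant,False
21,dr2,ic50,41.5,37.0,46.0,uM,ok,False
trolox,dr2,ic50,155.0,150.0,160.0,uM,ok,True
aesculin,dr2,ic50,795.0,730.0,860.0,uM,ok,True
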