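compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard
5,bcb,ic50,165.0,140.0,190.0,uM,ok,False
7,bcb,ic50,320.0,270.0,370.0,uM,ok,False
9,bcb,ic50,565.0,350.0,780.0,uM,ok,False
10,bcb,ic50,48.0,40.0,56.0,uM,ok,False
11,bcb,ic50,560.0,470.0,650.0,uM,ok,False
12,bcb,ic50,36.0,31.0,41.0,uM,ok,False
13,bcb,ic50,,,,uM,no_effect,False
18,bcb,ic50,,,,uM,no_effect,False
gallic_acid,bcb,ic50,275.0,210.0,340.0,uM,ok,True
quercetin,bcb,ic50,2.4,2.2,2.6,uM,ok,True
resveratrol,bcb,ic50,1.85,1.7,2.0,uM,ok,True
trolox,bcb,ic50,0.40,0.37,0.43,uM,ok,True
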