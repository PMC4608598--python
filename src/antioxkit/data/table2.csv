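compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard
5,dpph,k2_60min,1.8e-5,1.7e-5,1.9e-5,uM-1 s-1,ok,False
7,dpph,k2_60min,1.2e-5,1.1e-5,1.3e-5,uM-1 s-1,ok,False
9,dpph,k2_60min,1.1e-5,1.0e-5,1.2e-5,uM-1 s-1,ok,False
10,dpph,k2_60min,1.1e-5,1.0e-5,1.2e-5,uM-1 s-1,ok,False
11,dpph,k2_60min,1.0e-5,0.9e-5,1.1e-5,uM-1 s-1,ok,False
12,dpph,k2_60min,0.9e-5,0.8e-5,1.0e-5,uM-1 s-1,ok,False
13,dpph,k2_60min,1.2e-5,1.1e-5,1.3e-5,uM-1 s-1,ok,False
18,dpph,k2_60min,1.7e-5,1.6e-5,1.8e-5,uM-1 s-1,ok,False
19,dpph,k2_60min,2.0e-5,1.9e-5,2.1e-5,uM-1 s-1,ok,False
21,dpph,k2_60min,1.1e-5,1.0e-5,1.2e-5,uM-1 s-1,ok,False
ascorbic_acid,dpph,k2_60min,2.4e-5,2.3e-5,2.5e-5,uM-1 s-1,ok,True
gallic_acid,dpph,k2_60min,8.3e-5,8.0e-5,8.6e-5,uM-1 s-1,ok,True
quercetin,dpph,k2_60min,9.3e-5,9.0e-5,9.6e-5,uM-1 s-1,ok,True
trolox,dpph,k2_60min,4.5e-5,4.4e-5,4.6e-5,uM-1 s-1,ok,True
5,dpph,k2_24h,1.64e-6,1.55e-6,1.73e-6,uM-1 s-1,ok,False
7,dpph,k2_24h,6.5e-7,6.0e-7,7.0e-7,uM-1 s-1,ok,False
9,dpph,k2_24h,6.6e-7,6.0e-7,7.2e-7,uM-1 s-1,ok,False
10,dpph,k2_24h,5.8e-7,5.2e-7,6.4e-7,uM-1 s-1,ok,False
11,dpph,k2_24h,6.1e-7,5.5e-7,6.7e-7,uM-1 s-1,ok,False
12,dpph,k2_24h,5.8e-7,5.3e-7,6.3e-7,uM-1 s-1,ok,False
13,dpph,k2_24h,7.2e-7,6.5e-7,7.9e-7,uM-1 s-1,ok,False
18,dpph,k2_24h,9.4e-7,9.0e-7,9.8e-7,uM-1 s-1,ok,False
21,dpph,k2_24h,6.0e-7,5.5e-7,6.5e-7,uM-1 s-1,ok,False
aesculin,dpph,k2_24h,2.0e-9,1.5e-9,2.5e-9,uM-1 s-1,ok,True
scopoletin,dpph,k2_24h,2.0e-8,1.7e-8,2.3e-8,uM-1 s-1,ok,True
resveratrol,dpph,k2_24h,6.9e-7,6.5e-7,7.3e-7,uM-1 s-1,ok,True
curcumin,dpph,k2_24h,1.79e-6,1.75e-6,1.83e-6,uM-1 s-1,ok,True
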