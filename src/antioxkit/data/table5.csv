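compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard
5,bcb,k_prime,4.5e-3,4.2e-3,4.8e-3,uM-1,ok,False
7,bcb,k_prime,2.6e-2,2.5e-2,2.7e-2,uM-1,ok,False
9,bcb,k_prime,1.7e-3,1.6e-3,1.8e-3,uM-1,ok,False
10,bcb,k_prime,5.7e-3,5.3e-3,6.1e-3,uM-1,ok,False
11,bcb,k_prime,1.9e-3,1.8e-3,2.0e-3,uM-1,ok,False
12,bcb,k_prime,2.9e-2,2.6e-2,3.2e-2,uM-1,ok,False
gallic_acid,bcb,k_prime,3.8e-3,3.6e-3,4.0e-3,uM-1,ok,True
quercetin,bcb,k_prime,3.5e-1,3.4e-1,3.6e-1,uM-1,ok,True
resveratrol,bcb,k_prime,3.7e-1,3.5e-1,3.9e-1,uM-1,ok,True
trolox,bcb,k_prime,2.1,2.0,2.2,uM-1,ok,True
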