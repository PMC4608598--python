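compound_id,assay_id,metric,estimate,ci_low,ci_high,units,qualifier,is_standard,conc_uM
ascorbic_acid,caa,caa_value,71.0,71.0,71.0,dimensionless,ok,True,62.5
ascorbic_acid,caa,caa_value,79.9,79.9,79.9,dimensionless,ok,True,31.25
gallic_acid,caa,caa_value,76.9,76.9,76.9,dimensionless,ok,True,62.5
gallic_acid,caa,caa_value,85.1,85.1,85.1,dimensionless,ok,True,31.25
5,caa,caa_value,-26.9,-26.9,-26.9,dimensionless,ok,False,62.5
5,caa,caa_value,62.8,62.8,62.8,dimensionless,ok,False,31.25
7,caa,caa_value,41.5,41.5,41.5,dimensionless,ok,False,62.5
7,caa,caa_value,68.5,68.5,68.5,dimensionless,ok,False,31.25
9,caa,caa_value,73.5,73.5,73.5,dimensionless,ok,False,62.5
9,caa,caa_value,79.8,79.8,79.8,dimensionless,ok,False,31.25
10,caa,caa_value,65.0,65.0,65.0,dimensionless,ok,False,62.5
10,caa,caa_value,76.9,76.9,76.9,dimensionless,ok,False,31.25
11,caa,caa_value,75.4,75.4,75.4,dimensionless,ok,False,62.5
11,caa,caa_value,47.6,47.6,47.6,dimensionless,ok,False,31.25
12,caa,caa_value,-152.3,-152.3,-152.3,dimensionless,ok,False,31.25
12,caa,caa_value,-258.5,-258.5,-258.5,dimensionless,ok,False,15.625
13,caa,caa_value,77.1,77.1,77.1,dimensionless,ok,False,62.5
13,caa,caa_value,46.0,46.0,46.0,dimensionless,ok,False,31.25
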