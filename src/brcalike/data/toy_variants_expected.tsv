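variant_id	decision	reasons
V01	kept	
V02	excluded	synonymous;low_impact
V03	kept	
V04	excluded	low_impact
V05	excluded	predicted_benign
V06	kept	
V07	kept	
V08	excluded	common
V09	kept	
V10	kept	
V11	excluded	brca_not_pathogenic_or_vus
V12	excluded	brca_not_pathogenic_or_vus
V13	kept	
V14	excluded	synonymous;low_impact
V15	excluded	predicted_benign
V16	kept	
V17	excluded	low_impact
V18	excluded	common
V19	kept	
V20	kept	
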