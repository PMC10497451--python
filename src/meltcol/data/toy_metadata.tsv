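sample_id	compartment	day	is_control
SS_D1	surface_snow	1	false
BS_D1	bulk_snow	1	false
SO_D1	soil	1	false
SS_D4	surface_snow	4	false
BS_D4	bulk_snow	4	false
SO_D4	soil	4	false
SS_D8	surface_snow	8	false
BS_D8	bulk_snow	8	false
SO_D8	soil	8	false
SS_D11	surface_snow	11	false
BS_D11	bulk_snow	11	false
SO_D11	soil	11	false
SS_D15	surface_snow	15	false
BS_D15	bulk_snow	15	false
SO_D15	soil	15	false
SS_D19	surface_snow	19	false
BS_D19	bulk_snow	19	false
SO_D19	soil	19	false
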