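patient_id	time_days	event
P01	636.0	0
P04	287.0	1
P12	101.0	1
P13	239.0	1
P14	359.0	1
P15	219.0	1
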