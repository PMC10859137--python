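condition	vocabulary	code	match_mode
frozen_shoulder	ICD10	M75.0	prefix
frozen_shoulder	OPCS4	W78.1	exact
frozen_shoulder	GP	N210.	exact
frozen_shoulder	SELF	1478	exact
dupuytren	ICD10	M72.0	prefix
dupuytren	OPCS4	T52.1	exact
dupuytren	GP	N223.	exact
dupuytren	SELF	1544	exact
trigger_finger	ICD10	M65.3	prefix
trigger_finger	OPCS4	T72.3	exact
trigger_finger	GP	N2234	exact
trigger_finger	SELF	1619	exact
carpal_tunnel	ICD10	G56.0	prefix
carpal_tunnel	OPCS4	A65.1	exact
carpal_tunnel	GP	F3321	exact
carpal_tunnel	SELF	1541	exact
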