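sample_id	group	condition	replicate	class_label
GSM269814	T6	well watered	1	1
GSM269815	T6	drought	1	0
GSM269816	T8	well watered	1	1
GSM269817	T8	drought	1	0
GSM269822	T6	well watered	2	1
GSM269823	T6	drought	2	0
GSM269824	T8	well watered	2	1
GSM269825	T8	drought	2	0
GSM269830	T6	well watered	3	1
GSM269831	T6	drought	3	0
GSM269832	T8	well watered	3	1
GSM269833	T8	drought	3	0
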