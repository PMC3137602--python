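sample_id	group	condition	replicate	class_label
GSM269812	WT	well watered	1	1
GSM269813	WT	drought	1	0
GSM269818	C2	well watered	1	1
GSM269819	C2	drought	1	0
GSM269820	WT	well watered	2	1
GSM269821	WT	drought	2	0
GSM269826	C2	well watered	2	1
GSM269827	C2	drought	2	0
GSM269828	WT	well watered	3	1
GSM269829	WT	drought	3	0
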