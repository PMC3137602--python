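rank	probe_id	orf
1	262128_at	At1g52690
2	264580_at	At1g05340
3	258499_at	At3g02540
4	258239_at	At3g27690
5	266462_at	At2g47770
6	258347_at	At3g17520
7	247095_at	At5g66400
8	247723_at	At5g59220
9	262382_at	At1g72920
10	248352_at	At5g52300
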