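rank	probe_id	orf
1	248352_at	At5g52300
2	247723_at	At5g59220
3	249052_at	At5g44420
4	265342_at	At2g18300
5	257365_x_at	At2g26020
6	266743_at	At2g02990
7	258897_at	At3g05730
8	266462_at	At2g47770
9	248218_at	At5g53710
10	262347_at	At1g64110
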