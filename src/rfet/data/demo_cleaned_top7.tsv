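rank	probe_id	orf
1	249052_at	At5g44420
2	265342_at	At2g18300
3	257365_x_at	At2g26020
4	266743_at	At2g02990
5	258897_at	At3g05730
6	248218_at	At5g53710
7	262347_at	At1g64110
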