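0
3
-3
-6
6
9
-9
-12
12
15
-15
-18
-21
18
21
24
27
-24
-27
-30
-33
30
33
36
39
42
-36
-39
-42
-45
-48
45
48
51
54
57
60
-51
-54
-57
-60
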