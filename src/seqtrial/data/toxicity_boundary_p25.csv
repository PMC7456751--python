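# Abbreviated sequential toxicity stopping boundary, monitored toxicity
# probability 0.25, stated level 0.01.  Change points (n_observed,
# stop_count); between change points the boundary is the step value at
# the most recent listed n.  No stopping is possible below n = 5.
n,stop_count
5,2
6,3
8,4
10,5
12,6
14,7
16,8
18,9
20,10
23,11
25,12
28,13
52,22
55,23
79,31
82,32
107,40
110,41
158,56
161,57
164,58
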