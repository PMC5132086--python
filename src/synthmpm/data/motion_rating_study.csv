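# Forced-choice rating study: 12 motion-affected MPM datasets, 5 expert raters.
# pct_r1 / pct_mt: percentage of raters selecting the synthetic R1 / MT map as
# having lower artefact levels than the measured map.
participant,pct_r1,pct_mt
1,0,100
2,100,20
3,0,100
4,20,40
5,80,20
6,20,100
7,80,0
8,40,80
9,0,100
10,100,0
11,60,0
12,20,80
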