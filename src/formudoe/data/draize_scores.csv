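group,timepoint_h,erythema,edema
Gauze pad,1,0,0
Gauze pad,24,0,0
Gauze pad,48,0,0
Gauze pad,72,0,0
5% SLS solution,1,1.5,0
5% SLS solution,24,1.5,0
5% SLS solution,48,1.25,0
5% SLS solution,72,1,0
Blank proniosomes,1,0,0
Blank proniosomes,24,0,0
Blank proniosomes,48,0,0
Blank proniosomes,72,0,0
0.1% FLP,1,0,0
0.1% FLP,24,0,0
0.1% FLP,48,0,0
0.1% FLP,72,0,0
0.5% FLP,1,0,0
0.5% FLP,24,0,0
0.5% FLP,48,0,0
0.5% FLP,72,0,0
1% FLP,1,0,0
1% FLP,24,0,0
1% FLP,48,0,0
1% FLP,72,0,0
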