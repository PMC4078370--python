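Patient number,complete_metabolic_response,fdg_avid,has_post_scan,uptake_separable,glucose_baseline,glucose_post
1,0,1,1,1,5.2,5.6
2,0,1,1,1,6.1,5.9
3,1,1,1,1,5.4,5.1
4,0,1,1,1,4.9,5.3
5,0,1,1,1,5.8,6.2
6,0,1,1,1,20.4,21.1
7,0,1,1,1,6.4,5.7
8,0,1,1,1,5.1,4.8
9,0,1,1,0,5.6,6.0
10,1,1,1,1,5.3,5.5
11,1,1,1,1,4.7,5.2
12,1,1,1,1,6.2,5.8
13,0,0,1,1,5.9,5.4
14,0,1,1,1,5.0,5.7
15,0,1,0,1,5.5,6.1
16,0,1,1,1,6.0,5.2
17,0,1,1,1,5.3,4.9
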