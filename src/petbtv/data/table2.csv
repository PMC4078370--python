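Patient,Pre40|Post90,Pre40|Post80,Pre40|Post70,Pre40|Post60,Pre50|Post90,Pre50|Post80,Pre50|Post70,Pre50|Post60
1,100.0,87.5,87.0,83.0,50.0,68.8,66.7,64.0
2,100.0,100.0,100.0,68.9,100.0,100.0,100.0,54.5
4,100.0,100.0,100.0,95.9,100.0,16.7,87.0,81.6
5,100.0,100.0,100.0,100.0,100.0,100.0,100.0,88.5
7,0.0,0.0,6.3,18.2,0.0,0.0,0.0,6.8
8,100.0,100.0,100.0,100.0,100.0,100.0,100.0,100.0
14,100.0,100.0,100.0,90.0,100.0,100.0,81.8,70.0
16,100.0,100.0,100.0,93.4,100.0,100.0,95.0,82.9
17,50.0,68.8,60.0,51.8,50.0,43.8,40.0,35.1
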