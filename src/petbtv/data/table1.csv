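Patient number,Pre-treatment SUVmax,Post-treatment SUVmax,GTV,Pre40%,Pre50%,Post90%,Post80%,Post70%,Post60%
1,7.6,4.2,57.6,28.9,19.8,0.2,1.6,6.9,14.7
2,8.4,7.2,80.2,31.6,18.7,0.1,0.3,1.7,16.7
3,6.4,mCR,14.5,7.4,3.8,,,,
4,10.6,5.7,41.9,15.6,9.0,0.1,0.6,2.3,4.9
5,15.6,6.2,44.9,15.7,10.5,0.1,0.1,0.9,2.6
6,13.2,±,55.2,8.1,3.4,,,,
7,6.2,3.6,38.0,22.4,12.1,0.1,0.3,1.6,4.4
8,11.9,7.5,27.2,13.4,5.4,0.1,0.6,1.4,2.6
9,4.0,7.9,28.6,§,§,§,§,§,§
10,9.1,mCR,49.9,34.2,9.2,,,,
11,10.0,mCR,19.3,4.8,2.5,,,,
12,9.4,mCR,14.0,6,3.2,,,,
13,¢,¢,10.6,¢,¢,¢,¢,¢,¢
14,4.1,2.5,22.3,11.0,5.9,0.1,0.3,2.2,4.0
15,¤,¤,40.8,¤,¤,¤,¤,¤,¤
16,9.3,5.1,32.9,21.8,15.7,0.2,1.3,4,7.6
17,6.5,3.2,26.6,19.0,11.8,0.2,1.6,5.5,11.4
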