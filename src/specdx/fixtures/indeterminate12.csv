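case,truth,infiltration_index,fs_call
13,MIA,1.0,INDETERMINATE
15,MIA,0.5,INDETERMINATE
25,IAC,3.8,INDETERMINATE
26,MIA,0.0,INDETERMINATE
27,MIA,0.0,INDETERMINATE
34,AAH,0.5,INDETERMINATE
48,IAC,0.6,INDETERMINATE
49,MIA,3.2,INDETERMINATE
50,MIA,0.0,INDETERMINATE
51,MIA,4.5,INDETERMINATE
52,IAC,5.0,INDETERMINATE
64,IAC,2.6,INDETERMINATE
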