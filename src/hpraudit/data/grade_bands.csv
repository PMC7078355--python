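label,total_min,total_max,chapter_min
A,85.1,100.0,60.0
B,70.1,85.0,50.0
C,55.1,70.0,
D,0.0,55.0,
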