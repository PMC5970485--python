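Gene,Number of activators,Number of repressors,Threshold %
A,1,1,100.0
B,1,0,50.0
C,1,0,100.0
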