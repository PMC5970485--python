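Cell,Class,A,B,C
0,E3,1,0,0
1,mid,1,1,0
2,mid,1,1,1
3,E7,0,1,1
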