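value,count
0,14641
1,5218
2,285
3,45
4,23
5,8
6,9
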