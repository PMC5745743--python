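*Vertices 3
1 "A"
2 "B"
3 "C"
*Edges
1 2
2 3
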