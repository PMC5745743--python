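*Vertices 6
1 "hub"
2 "leaf1"
3 "leaf2"
4 "leaf3"
5 "leaf4"
6 "leaf5"
*Edges
1 2
1 3
1 4
1 5
1 6
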