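PW1	first toy pathway	T1	T2	T3
PW2	second toy pathway	T3	T4
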