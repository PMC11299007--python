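Evidence,Weight,Proposition 1,Proposition 2,Proposition 3
Evidence 1,10,90%,0,0
Evidence 2,8,0,90%,0
Evidence 3,5,0,0,90%
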