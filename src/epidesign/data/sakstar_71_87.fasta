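>SakSTAR_71-87 staphylokinase immunodominant C3 fragment (residues 71-87)
TAYKEFRVVELDPSAKI
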